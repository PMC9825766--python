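"""Generate a small synthetic multi-tissue pcHi-C study on disk.

Writes a random genome (FASTA), gene annotation (BED), per-tissue coverage
tracks (bedGraph) and per-tissue interaction tables (BEDPE-like TSV with an
FDR column), with a shared sequence motif and coverage enrichment planted at
positive anchors.
"""

import json
import tempfile
from pathlib import Path

from loopnet.simulate import SimulationConfig, simulate_study

outdir = Path(tempfile.mkdtemp(prefix="loopnet_study_"))
cfg = SimulationConfig(n_chroms=2, chrom_len=1_200_000, tissues=("GM", "H1"),
                       n_positives=100, seed=42)
manifest = simulate_study(cfg, outdir, itypes=("PE",))

print(f"study written under {outdir}")
print(json.dumps({k: v for k, v in manifest.items() if not k.startswith('_')}, indent=1))
for key, data in manifest["_tissue_data"].items():
    n_pos = int(data.truth.sum())
    print(f"{key}: {len(data.interactions)} candidate interactions "
          f"({n_pos} true positives, private motif {data.private_motif})")
# Each tissue gets n_positives true interactions (FDR < 0.1) plus a 2x pool
# of non-significant candidates (FDR > 0.5) for GC-matched negative sampling.
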