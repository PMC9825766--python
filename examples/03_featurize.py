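"""Turn a labeled dataset into model-ready feature bundles.

S: per-anchor one-hot sequence (2000 x 4, two anchors stacked as channels);
R: 21 windowed, CPM-normalized coverage values per anchor per track
(1000-bp window slid by 50 bp); D: anchor distance scaled by the 1-Mb bound.
"""

from loopnet.features import build_feature_bundles
from loopnet.interactions import build_labeled_dataset
from loopnet.simulate import (
    SimulationConfig, generate_genome, generate_tissue_interactions, generate_tracks,
)

cfg = SimulationConfig(n_chroms=2, chrom_len=1_200_000, tissues=("GM",),
                       n_positives=50, seed=3)
genome, _ = generate_genome(cfg)
tissue = generate_tissue_interactions(cfg, genome, "GM")
tracks = generate_tracks(cfg, genome, tissue)

dataset = build_labeled_dataset(tissue.interactions, genome, seed=1)
bundles = build_feature_bundles(dataset, reference=genome,
                                tracks=list(tracks.values()), active=("S", "R", "D"))
for name, arr in bundles.arrays.items():
    print(f"{name}: shape {arr.shape}, dtype {arr.dtype}")
print(f"labels: {int(bundles.labels.sum())} of {len(bundles)} positive")
# R is (interactions, 2 anchors, 21 windows, 4 marks); the 21 comes from
# (2000 - 1000) / 50 + 1 windows across each standardized anchor.
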