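"""The LRz meta-statistic across heterogeneous fractionation datasets.

Simulates a gene x dataset matrix of neurite/soma localization ratios in
which every dataset reports the same latent gene effects through its own
affine distortion (scale and offset), then shows that within-dataset
z-normalization followed by the per-gene median removes the distortions.
"""

import numpy as np

import rnaloc as rl

rng = np.random.default_rng(11)
effects = rng.normal(size=300)

undistorted, _ = rl.generate_multidataset_lr(
    300, 6, gene_effects=effects,
    dataset_scales=np.ones(6), dataset_offsets=np.zeros(6),
    noise_sd=0.0, seed=12,
)
distorted, _ = rl.generate_multidataset_lr(
    300, 6, gene_effects=effects,
    dataset_scales=rng.uniform(0.2, 5.0, 6),
    dataset_offsets=rng.normal(0.0, 3.0, 6),
    noise_sd=0.0, seed=12,
)

lrz_plain = rl.compute_lrz(undistorted)
lrz_dist = rl.compute_lrz(distorted)
dev = (lrz_plain.lrz - lrz_dist.lrz).abs().max()
print(f"datasets pooled: 6; genes: 300")
print(f"max |LRz difference| between distorted and undistorted inputs: {dev:.2e}")
top = lrz_plain.lrz.sort_values(ascending=False).head(3)
print("most neurite-enriched genes by LRz:")
for gene, value in top.items():
    print(f"  {gene}: LRz = {value:.2f}")
# LRz > 0 marks neurite-enriched transcripts, LRz < 0 soma-enriched ones;
# because each dataset is z-normalized before the median, laboratory- or
# protocol-specific scales and offsets cancel exactly.
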