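"""Hierarchical clustering of log2-ratio profiles with Pearson distance.

Builds per-platform, per-sex log2-ratio profiles for the significant miRNAs
of a simulated study and clusters them with average linkage on 1 - r,
exporting the tree as Newick.
"""

import pandas as pd

from mirxplat import (
    SimulationConfig,
    clamp_negatives,
    de_table,
    export_tree,
    hca,
    percentile_scale,
    quantile_normalize,
    simulate_two_platforms,
    summarize_replicates,
)
from mirxplat.synthetic_data import PlatformBias

cfg = SimulationConfig(
    n_mirnas=200,
    noise_sd=0.3,
    planted_effects={
        "sim-miR-0001": (2.5, None),
        "sim-miR-0002": (2.4, None),
        "sim-miR-0003": (2.0, "M"),
        "sim-miR-0004": (1.9, "M"),
        "sim-miR-0005": (-2.0, "F"),
    },
    platform_bias_a=PlatformBias(gc_midpoint=-1e9, gc_slope=1.0),
    platform_bias_b=PlatformBias(gc_midpoint=-1e9, gc_slope=1.0),
    seed=1,
)
mat_a, mat_b, _ = simulate_two_platforms(cfg)
norm = {"A": quantile_normalize(mat_a),
        "B": summarize_replicates(clamp_negatives(percentile_scale(mat_b)))}

contrasts = {"M": ("M_cRaf", "M_WT"), "F": ("F_cRaf", "F_WT")}
profiles = pd.DataFrame(
    {
        f"{platform}_{sex}": de_table(norm[platform], contrast)["log2_ratio"]
        for platform in ("A", "B")
        for sex, contrast in contrasts.items()
    }
)
# cluster the planted miRNAs plus a few nulls for contrast
rows = [f"sim-miR-{i + 1:04d}" for i in range(8)]
tree = hca(profiles.loc[rows], linkage="average")

print(export_tree(tree))
print()
print(tree.merge_table().round(4).to_string(index=False))
print()
print(
    "Leaves merging at low height have correlated regulation profiles: the\n"
    "male-restricted effects pair first because their profile shape (high in\n"
    "M, flat in F) is distinctive on both platforms. Uniformly regulated\n"
    "miRNAs have nearly flat profiles, so their pairwise correlations are\n"
    "noise-driven -- Pearson distance clusters by profile shape, not by\n"
    "effect magnitude, which is exactly why it separates sex-specific from\n"
    "global regulation."
)
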