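"""Welch's t-test differential expression with the compound significance filter.

Plants three effects (one in both sexes, one male-only, one female-only) and
recovers them with per-sex contrasts of transgenic vs wild-type groups; the
filter keeps features with p < 0.05, |log2 ratio| >= 1.5 and mean signal
above the 50th percentile.
"""

from mirxplat import SimulationConfig, de_table, filter_significant, quantile_normalize, simulate_two_platforms
from mirxplat.synthetic_data import PlatformBias

cfg = SimulationConfig(
    n_mirnas=300,
    noise_sd=0.3,
    planted_effects={
        "sim-miR-0001": (2.5, None),
        "sim-miR-0002": (2.0, "M"),
        "sim-miR-0003": (2.0, "F"),
    },
    platform_bias_a=PlatformBias(gc_midpoint=-1e9, gc_slope=1.0),  # fully sensitive
    seed=1,
)
mat_a, _, truth = simulate_two_platforms(cfg)
norm = quantile_normalize(mat_a)

for sex, contrast in {"M": ("M_cRaf", "M_WT"), "F": ("F_cRaf", "F_WT")}.items():
    table = de_table(norm, contrast)
    sig = filter_significant(table)
    print(f"contrast {contrast[0]} vs {contrast[1]}: {len(sig)} significant")
    print(sig[["p", "log2_ratio", "mean_all"]].round(4).to_string())
    print()

print(
    "The log2_ratio column is the signal logarithm ratio of group means; the\n"
    "male-only effect (sim-miR-0002) appears in the M contrast only and the\n"
    "female-only effect (sim-miR-0003) in the F contrast only, while the\n"
    "shared effect (sim-miR-0001) is recovered in both."
)
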