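"""Simulate a two-platform miRNA study and apply each vendor's normalization.

The simulated design is 4 groups (male/female x wild-type/transgenic, n = 6):
platform A reports one value per miRNA and sample and is quantile-normalized;
platform B reports 20 replicate spots per miRNA (some background-corrected
below zero) and goes through 75th-percentile scaling, clamping of
non-positive values at 0.01, and per-miRNA median summarization.
"""

from mirxplat import (
    SimulationConfig,
    clamp_negatives,
    percentile_scale,
    quantile_normalize,
    simulate_two_platforms,
    summarize_replicates,
)

cfg = SimulationConfig(
    n_mirnas=100,
    planted_effects={"sim-miR-0001": (2.0, None)},
    seed=1,
)
raw_a, raw_b, truth = simulate_two_platforms(cfg)

norm_a = quantile_normalize(raw_a)
norm_b = summarize_replicates(clamp_negatives(percentile_scale(raw_b)))

print(f"platform A raw: {raw_a.values.shape} (miRNA x sample)")
print(f"platform B raw: {raw_b.values.shape} (spot-level, 20 spots per miRNA)")
print(f"negative spots on B: {(raw_b.values < 0).to_numpy().mean():.1%}")
print(f"platform B summarized: {norm_b.values.shape}")
print()
print("provenance of the platform B arm:")
for line in norm_b.log:
    print(" ", line)
print()
print(
    "After quantile normalization every platform A sample has the identical\n"
    "signal distribution; after percentile scaling every platform B sample\n"
    "shares one 75th-percentile level, and replicate-spot medians absorb the\n"
    "negative background-corrected spots."
)
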