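"""Cross-platform detection overlap and the GC-content discordance diagnostic.

Platform A is GC-sensitive (logistic detectability midpoint at GC 45%),
platform B broadly sensitive; the overlap summary quantifies how few of the
shared miRNAs both platforms call detected, and the GC report shows that
platform-B-exclusive miRNAs sit at lower GC than commonly detected ones.
"""

import numpy as np

from mirxplat import SimulationConfig, call_detected, gc_discordance, overlap_stats, quantile_normalize
from mirxplat import clamp_negatives, percentile_scale, summarize_replicates, simulate_two_platforms

cfg = SimulationConfig(n_mirnas=586, seed=1)  # a realistically sized shared universe
raw_a, raw_b, truth = simulate_two_platforms(cfg)
norm_a = quantile_normalize(raw_a)
norm_b = summarize_replicates(clamp_negatives(percentile_scale(raw_b)))

calls_a = call_detected(norm_a)
calls_b = call_detected(norm_b)
universe = list(truth.gc.index)

for group in ("M_WT", "M_cRaf"):
    s = overlap_stats(calls_a.detected_in(group), calls_b.detected_in(group), universe)
    print(
        f"{group}: A detected {s.to_dict()['n_detected_a']} ({s.fraction_a:.0%}), "
        f"B detected {s.to_dict()['n_detected_b']} ({s.fraction_b:.0%}), "
        f"common {s.to_dict()['n_common']} ({s.fraction_common:.0%} of universe)"
    )

rep = gc_discordance(calls_a.detected_any(), calls_b.detected_any(), truth.gc.to_dict())
print()
print(f"B-exclusive miRNAs: n={len(rep.only_b.members)}, mean GC {rep.only_b.gc_mean:.1f}%")
print(f"shared miRNAs:      n={len(rep.shared.members)}, mean GC {rep.shared.gc_mean:.1f}%")
print()
print(
    "The GC-sensitive platform misses low-GC miRNAs: the features only the\n"
    "broadly sensitive platform detects have markedly lower GC content than\n"
    "the commonly detected set -- the structural signature of platform\n"
    "discordance driven by probe hybridization chemistry."
)
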