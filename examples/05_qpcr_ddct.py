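"""ddCt quantification of a simulated qPCR validation arm.

Ct values are normalized to the U6 small nuclear RNA reference within each
sample (dCt); the difference of group-mean dCt between transgenic and
wild-type animals (ddCt) gives the fold change as 2^(-ddCt).
"""

from mirxplat import SimulationConfig, ddct_fold_change, simulate_qpcr, simulate_two_platforms

cfg = SimulationConfig(
    n_mirnas=50,
    planted_effects={"sim-miR-0001": (2.0, None), "sim-miR-0002": (1.5, "M")},
    qpcr_noise_sd=0.2,
    seed=1,
)
_, _, truth = simulate_two_platforms(cfg)
ct = simulate_qpcr(cfg, truth)
groups = dict(zip(ct["sample"], ct["group"]))

print(f"Ct table: {len(ct)} measurements, assays = {sorted(ct['assay'].unique())}")
for sex, contrast in {"M": ("M_cRaf", "M_WT"), "F": ("F_cRaf", "F_WT")}.items():
    res = ddct_fold_change(ct.drop(columns="group"), groups, contrast)
    print(f"\ncontrast {contrast[0]} vs {contrast[1]}:")
    for assay, r in sorted(res.items()):
        print(
            f"  {assay:14s} ddCt={r.ddct:+.2f}  log2FC={r.log2_fold_change:+.2f}  "
            f"FC={r.fold_change:5.2f}  p={r.p:.4f}"
        )

print(
    "\nA ddCt of -2 corresponds to a 4-fold up-regulation. The male-restricted\n"
    "effect (sim-miR-0002) is recovered near its planted 2^1.5 = 2.8-fold in\n"
    "males and stays near 1-fold (non-significant) in females; the U6\n"
    "reference is exactly 1.0 by construction."
)
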