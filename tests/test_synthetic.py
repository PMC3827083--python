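"""The synthetic two-platform generator: determinism, planted-effect
recovery, negative spots, GC-dependent detection bias, and the qPCR arm."""

import numpy as np
import pandas as pd
import pytest

from mirxplat.diffexp import ddct_fold_change
from mirxplat.synthetic_data import (
    GROUPS,
    PlatformBias,
    SimulationConfig,
    SimulationError,
    simulate_qpcr,
    simulate_two_platforms,
)

FULL_SENSITIVITY = PlatformBias(gc_midpoint=-1e9, gc_slope=1.0)


def cfg_all_detectable(**kw):
    defaults = dict(
        n_mirnas=100,
        platform_bias_a=FULL_SENSITIVITY,
        platform_bias_b=FULL_SENSITIVITY,
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(n_per_group=1), dict(noise_sd=-0.1), dict(negative_rate=1.5)],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(SimulationError):
            SimulationConfig(**kw)

    def test_planted_effect_on_unknown_mirna(self):
        cfg = cfg_all_detectable(planted_effects={"nonexistent": (2.0, None)})
        with pytest.raises(SimulationError, match="unknown miRNA"):
            simulate_two_platforms(cfg)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = cfg_all_detectable(n_mirnas=50, planted_effects={"sim-miR-0001": (2.0, "F")})
        a1, b1, t1 = simulate_two_platforms(cfg)
        a2, b2, t2 = simulate_two_platforms(cfg)
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_frame_equal(b1.values, b2.values)
        pd.testing.assert_frame_equal(t1.true_log2fc, t2.true_log2fc)
        pd.testing.assert_frame_equal(
            simulate_qpcr(cfg, t1), simulate_qpcr(cfg, t2)
        )

    def test_different_seed_differs(self):
        a1, _, _ = simulate_two_platforms(cfg_all_detectable(seed=0))
        a2, _, _ = simulate_two_platforms(cfg_all_detectable(seed=1))
        assert not a1.values.equals(a2.values)


class TestSignals:
    def test_noiseless_no_effects_all_ratios_zero(self):
        cfg = cfg_all_detectable(noise_sd=0.0, spot_noise_sd=0.0, negative_rate=0.0)
        mat_a, _, _ = simulate_two_platforms(cfg)
        log2 = np.log2(mat_a.values)
        groups = mat_a.groups()
        for g1 in GROUPS:
            for g2 in GROUPS:
                ratios = log2[groups[g1]].mean(axis=1) - log2[groups[g2]].mean(axis=1)
                np.testing.assert_allclose(ratios, 0.0, atol=1e-12)

    def test_planted_effect_recovered_within_3_se(self):
        # closed-form SE of the group-mean log2-ratio estimator: sd*sqrt(2/n)
        cfg = cfg_all_detectable(
            n_mirnas=200, noise_sd=0.3, planted_effects={"sim-miR-0001": (2.0, None)}, seed=7
        )
        mat_a, _, _ = simulate_two_platforms(cfg)
        log2 = np.log2(mat_a.values)
        groups = mat_a.groups()
        est = (
            log2.loc["sim-miR-0001", groups["M_cRaf"]].mean()
            - log2.loc["sim-miR-0001", groups["M_WT"]].mean()
        )
        se = 0.3 * np.sqrt(2.0 / 6.0)
        assert abs(est - 2.0) < 3.0 * se

    def test_sample_layout(self):
        mat_a, mat_b, _ = simulate_two_platforms(cfg_all_detectable())
        assert mat_a.values.shape == (100, 24)
        assert set(mat_a.sample_meta["group"]) == set(GROUPS)
        assert mat_b.values.index.nlevels == 2
        assert mat_b.values.shape == (100 * 20, 24)


class TestPlatformB:
    def test_negative_rate_realized(self):
        cfg = cfg_all_detectable(negative_rate=0.1, seed=3)
        _, mat_b, _ = simulate_two_platforms(cfg)
        frac_neg = float((mat_b.values < 0).mean().mean())
        assert 0.07 < frac_neg < 0.13

    def test_no_negatives_when_rate_zero(self):
        _, mat_b, _ = simulate_two_platforms(cfg_all_detectable(negative_rate=0.0))
        assert (mat_b.values > 0).all().all()


class TestDetectionBias:
    def test_low_gc_less_detectable_on_platform_a(self):
        # platform A's logistic midpoint at GC 45% leaves low-GC miRNAs to
        # platform B: B-exclusive detectable miRNAs have lower mean GC than
        # commonly detectable ones
        cfg = SimulationConfig(
            n_mirnas=2000,
            platform_bias_a=PlatformBias(gc_midpoint=45.0, gc_slope=0.25),
            platform_bias_b=PlatformBias(gc_midpoint=25.0, gc_slope=0.15),
            seed=11,
        )
        _, _, truth = simulate_two_platforms(cfg)
        det = truth.detectable
        common = truth.gc[det["A"] & det["B"]]
        b_only = truth.gc[det["B"] & ~det["A"]]
        assert len(common) > 50 and len(b_only) > 50
        assert b_only.mean() < common.mean()
        # one-sided Welch test on the GC difference
        from mirxplat.diffexp import welch_t

        t, _, p = welch_t(b_only, common)
        assert t < 0 and p / 2 < 0.001


class TestQpcr:
    def test_noiseless_ddct_recovers_planted_fc(self):
        cfg = cfg_all_detectable(
            noise_sd=0.0,
            qpcr_noise_sd=0.0,
            planted_effects={"sim-miR-0001": (2.0, None), "sim-miR-0002": (1.0, "M")},
        )
        _, _, truth = simulate_two_platforms(cfg)
        ct = simulate_qpcr(cfg, truth)
        groups = dict(zip(ct["sample"], ct["group"]))
        res = ddct_fold_change(ct.drop(columns="group"), groups, ("F_cRaf", "F_WT"))
        assert res["sim-miR-0001"].ddct == pytest.approx(-2.0)
        assert res["sim-miR-0001"].fold_change == pytest.approx(4.0)
        assert res["sim-miR-0002"].log2_fold_change == pytest.approx(0.0)  # M-restricted
        res_m = ddct_fold_change(ct.drop(columns="group"), groups, ("M_cRaf", "M_WT"))
        assert res_m["sim-miR-0002"].log2_fold_change == pytest.approx(1.0)

    def test_u6_constant_across_groups_noiseless(self):
        cfg = cfg_all_detectable(noise_sd=0.0, qpcr_noise_sd=0.0)
        _, _, truth = simulate_two_platforms(cfg)
        ct = simulate_qpcr(cfg, truth)
        u6 = ct[ct["assay"] == "U6"]["ct"]
        assert u6.nunique() == 1

    def test_noisy_recovery_within_3_se(self):
        cfg = cfg_all_detectable(
            noise_sd=0.0, qpcr_noise_sd=0.2, planted_effects={"sim-miR-0001": (2.0, None)}, seed=5
        )
        _, _, truth = simulate_two_platforms(cfg)
        ct = simulate_qpcr(cfg, truth)
        groups = dict(zip(ct["sample"], ct["group"]))
        res = ddct_fold_change(ct.drop(columns="group"), groups, ("M_cRaf", "M_WT"))
        # dCt variance = 2*sd^2 (target + reference noise); SE of ddCt over n=6/6
        se = np.sqrt(2 * 0.2**2) * np.sqrt(2.0 / 6.0)
        assert abs(res["sim-miR-0001"].log2_fold_change - 2.0) < 3.0 * se

    def test_array_and_qpcr_arms_agree_noiseless(self):
        # cross-method concordance: the two arms of a noiseless simulation
        # yield identical log2 fold changes
        from mirxplat.diffexp import de_table

        cfg = cfg_all_detectable(
            noise_sd=0.0, qpcr_noise_sd=0.0, planted_effects={"sim-miR-0003": (1.7, "F")}
        )
        mat_a, _, truth = simulate_two_platforms(cfg)
        de = de_table(mat_a, ("F_cRaf", "F_WT"))
        ct = simulate_qpcr(cfg, truth)
        groups = dict(zip(ct["sample"], ct["group"]))
        res = ddct_fold_change(ct.drop(columns="group"), groups, ("F_cRaf", "F_WT"))
        assert res["sim-miR-0003"].log2_fold_change == pytest.approx(
            de.loc["sim-miR-0003", "log2_ratio"]
        )
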