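"""Welch's t-test, the compound significance filter, and ddCt quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirxplat.diffexp import (
    DiffexpError,
    ddct_fold_change,
    de_table,
    filter_significant,
    welch_t,
)
from mirxplat.normalize import ExpressionMatrix
from mirxplat.synthetic_data import SimulationConfig, PlatformBias, simulate_two_platforms

finite_group = st.lists(
    st.floats(min_value=-1e4, max_value=1e4, allow_nan=False), min_size=2, max_size=12
)


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_equal_means(self):
        t, df, p = welch_t([5.0, 5.0], [5.0, 5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_example(self):
        # closed form: t = (12-22)/sqrt(4/3 + 4/3) = -6.1237, df = 4
        t, df, p = welch_t([10, 12, 14], [20, 22, 24])
        assert t == pytest.approx(-6.123724, abs=1e-5)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0036022, abs=1e-6)

    def test_antisymmetry(self):
        t1, df1, p1 = welch_t([1.0, 3.0, 4.0], [2.0, 8.0, 9.0, 10.0])
        t2, df2, p2 = welch_t([2.0, 8.0, 9.0, 10.0], [1.0, 3.0, 4.0])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_too_small_group(self):
        with pytest.raises(DiffexpError):
            welch_t([1.0], [1.0, 2.0])

    def test_against_reference_implementation(self):
        # 100 random small instances vs scipy's Welch test
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(2, 10, size=2)
            a = rng.normal(rng.normal(), rng.uniform(0.5, 3.0), size=na)
            b = rng.normal(rng.normal(), rng.uniform(0.5, 3.0), size=nb)
            t, df, p = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)

    @given(finite_group, finite_group)
    @settings(max_examples=50, deadline=None)
    def test_df_within_welch_satterthwaite_bounds(self, a, b):
        t, df, p = welch_t(a, b)
        assert 0.0 <= p <= 1.0
        if np.var(a, ddof=1) + np.var(b, ddof=1) > 0:
            assert min(len(a), len(b)) - 1 <= df + 1e-9
            assert df <= len(a) + len(b) - 2 + 1e-9


def four_group_config(**kw):
    defaults = dict(
        n_mirnas=50,
        n_per_group=6,
        noise_sd=0.0,
        platform_bias_a=PlatformBias(gc_midpoint=-1e9, gc_slope=1.0),
        platform_bias_b=PlatformBias(gc_midpoint=-1e9, gc_slope=1.0),
        negative_rate=0.0,
        spot_noise_sd=0.0,
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeTable:
    def test_noiseless_planted_ratio_exact(self):
        cfg = four_group_config(
            planted_effects={"sim-miR-0001": (2.0, None), "sim-miR-0002": (-1.0, "M")}
        )
        mat_a, _, _ = simulate_two_platforms(cfg)
        de_m = de_table(mat_a, ("M_cRaf", "M_WT"))
        de_f = de_table(mat_a, ("F_cRaf", "F_WT"))
        assert de_m.loc["sim-miR-0001", "log2_ratio"] == pytest.approx(2.0)
        assert de_f.loc["sim-miR-0001", "log2_ratio"] == pytest.approx(2.0)
        assert de_m.loc["sim-miR-0002", "log2_ratio"] == pytest.approx(-1.0)
        assert de_f.loc["sim-miR-0002", "log2_ratio"] == pytest.approx(0.0)
        assert de_m.loc["sim-miR-0003", "log2_ratio"] == pytest.approx(0.0)

    def test_sample_order_invariance(self):
        cfg = four_group_config(noise_sd=0.3, planted_effects={"sim-miR-0001": (2.0, None)})
        mat_a, _, _ = simulate_two_platforms(cfg)
        shuffled = ExpressionMatrix(
            values=mat_a.values[list(reversed(mat_a.values.columns))],
            sample_meta=mat_a.sample_meta,
        )
        t1 = de_table(mat_a, ("M_cRaf", "M_WT"))
        t2 = de_table(shuffled, ("M_cRaf", "M_WT"))
        pd.testing.assert_frame_equal(t1, t2)

    def test_group_without_samples(self, small_matrix):
        with pytest.raises(DiffexpError, match="no samples"):
            de_table(small_matrix, ("g1", "missing"))


class TestFilterSignificant:
    def toy_table(self):
        # engineered: exactly rows "a" and "b" pass all three gates at defaults
        return pd.DataFrame(
            {
                "p": [0.01, 0.001, 0.2, 0.01, 0.01],
                "log2_ratio": [2.0, -1.6, 3.0, 1.0, 2.5],
                "mean_all": [700.0, 650.0, 600.0, 620.0, 5.0],
            },
            index=["a", "b", "c", "d", "e"],
        )

    def test_exactly_two_survivors(self):
        sig = filter_significant(self.toy_table())
        assert sorted(sig.index) == ["a", "b"]

    def test_all_p_one_empty(self):
        t = self.toy_table()
        t["p"] = 1.0
        assert len(filter_significant(t)) == 0

    def test_each_gate_excludes_independently(self):
        # with the mean gate opened to the minimum, each remaining row fails
        # exactly one gate: "c" only p, "d" only fold change, "e" only mean
        sig = filter_significant(self.toy_table(), min_mean_percentile=0.0)
        assert "c" not in sig.index and "d" not in sig.index and "e" not in sig.index
        assert sorted(sig.index) == ["a", "b"]

    def test_linear_fc_gate(self):
        t = self.toy_table()
        # |FC|>3 excludes b (2^1.6 = 3.03 passes) but excludes a 2^2=4? no: both pass;
        # use a row at exactly log2 1.5 (FC 2.83) which passes the log2 gate but not |FC|>3
        t.loc["a", "log2_ratio"] = 1.5
        assert "a" in filter_significant(t).index
        assert "a" not in filter_significant(t, min_linear_fc=3.0).index

    def test_empty_table_rejected(self):
        with pytest.raises(DiffexpError):
            filter_significant(self.toy_table().iloc[:0])


class TestDdct:
    def tidy(self, case_dct, control_dct, u6=20.0):
        rows = []
        groups = {}
        for i, d in enumerate(case_dct):
            s = f"case_{i}"
            rows += [(s, "mirX", u6 + d), (s, "U6", u6)]
            groups[s] = "case"
        for i, d in enumerate(control_dct):
            s = f"ctrl_{i}"
            rows += [(s, "mirX", u6 + d), (s, "U6", u6)]
            groups[s] = "control"
        return pd.DataFrame(rows, columns=["sample", "assay", "ct"]), groups

    def test_hand_arithmetic(self):
        ct, groups = self.tidy([5.0, 5.0, 5.0], [7.0, 7.0, 7.0])
        res = ddct_fold_change(ct, groups, ("case", "control"))["mirX"]
        assert res.ddct == pytest.approx(-2.0)
        assert res.log2_fold_change == pytest.approx(2.0)
        assert res.fold_change == pytest.approx(4.0)

    def test_zero_ddct_fold_change_one(self):
        ct, groups = self.tidy([3.0, 3.0], [3.0, 3.0])
        res = ddct_fold_change(ct, groups, ("case", "control"))["mirX"]
        assert res.fold_change == pytest.approx(1.0)

    def test_reference_assay_fc_is_one(self):
        ct, groups = self.tidy([5.0, 4.0, 6.0], [7.0, 8.0, 6.0])
        res = ddct_fold_change(ct, groups, ("case", "control"))["U6"]
        assert res.log2_fold_change == 0.0
        assert res.p == 1.0

    def test_missing_reference(self):
        ct, groups = self.tidy([5.0, 5.0], [7.0, 7.0])
        ct = ct[ct["assay"] != "U6"]
        with pytest.raises(DiffexpError, match="reference"):
            ddct_fold_change(ct, groups, ("case", "control"))
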