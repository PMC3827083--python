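"""Welch's t-test differential expression and ddCt qPCR quantification.

Contrasts compare transgenic vs wild-type groups separately per sex. Fold
change is reported as the signal logarithm ratio (SLR): log2 of the ratio of
group means of linear signals, not the mean of per-sample log ratios. The
compound significance filter keeps features with p below a cutoff, absolute
SLR at or above a log2 threshold, and mean signal above a percentile of all
features' means. No multiple-testing correction gates by default; a
Benjamini-Hochberg q-value column is emitted for modern use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirxplat.normalize import ExpressionMatrix


class DiffexpError(ValueError):
    pass


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p). Identical groups with
    zero variance give t=0, p=1; zero variance with unequal means gives
    an infinite t and p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise DiffexpError(f"each group needs >= 2 values (got {na} and {nb})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0.0:
        df = float(na + nb - 2)
        if diff == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def de_table(
    m: ExpressionMatrix,
    contrast: tuple[str, str],
    use_log2_for_test: bool = True,
    clamp_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-miRNA Welch test and SLR for one (case, control) group contrast.

    Signals are clamped at ``clamp_floor`` before the log2 transform. The test
    statistic is computed on log2 signals by default (configurable); the SLR
    is always log2(mean case / mean control) on linear signals. ``mean_all``
    is the mean linear signal across the contrast's samples. Returns a
    DataFrame with columns t, df, p, q, log2_ratio, mean_all, significant
    (False until :func:`filter_significant`).
    """
    case, control = contrast
    groups = m.groups()
    for g in contrast:
        if g not in groups or len(groups[g]) == 0:
            raise DiffexpError(f"contrast group {g!r} has no samples")
    vals = m.values.mask(m.values <= 0, clamp_floor)
    a = vals[groups[case]]
    b = vals[groups[control]]
    test_a = np.log2(a) if use_log2_for_test else a
    test_b = np.log2(b) if use_log2_for_test else b

    rows = []
    for mirna in vals.index:
        t, df, p = welch_t(test_a.loc[mirna], test_b.loc[mirna])
        rows.append((t, df, p))
    out = pd.DataFrame(rows, index=vals.index, columns=["t", "df", "p"])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["log2_ratio"] = np.log2(a.mean(axis=1) / b.mean(axis=1))
    out["mean_all"] = pd.concat([a, b], axis=1).mean(axis=1)
    out["significant"] = False
    out.attrs["contrast"] = (case, control)
    return out


def filter_significant(
    de: pd.DataFrame,
    p_max: float = 0.05,
    min_abs_log2fc: float = 1.5,
    min_mean_percentile: float = 50.0,
    min_linear_fc: float | None = None,
) -> pd.DataFrame:
    """Apply the compound significance filter and return the passing subset.

    Keeps rows with p < p_max AND |SLR| >= min_abs_log2fc AND mean signal
    above the given percentile of all features' mean signals. Pass
    ``min_linear_fc`` (e.g. 3.0) to gate on linear fold change instead of the
    log2 threshold. Thresholds are recorded in ``.attrs``.
    """
    if de.empty:
        raise DiffexpError("empty DE table")
    if min_linear_fc is not None:
        fc_gate = 2.0 ** de["log2_ratio"].abs() > min_linear_fc
        fc_desc = f"|FC|>{min_linear_fc}"
    else:
        fc_gate = de["log2_ratio"].abs() >= min_abs_log2fc
        fc_desc = f"|log2FC|>={min_abs_log2fc}"
    mean_cut = np.percentile(de["mean_all"].to_numpy(), min_mean_percentile)
    keep = (de["p"] < p_max) & fc_gate & (de["mean_all"] > mean_cut)
    out = de.copy()
    out["significant"] = keep
    out = out[keep]
    out.attrs["filter"] = f"p<{p_max} AND {fc_desc} AND mean>{min_mean_percentile}th pct ({mean_cut:.4g})"
    return out


@dataclass(frozen=True)
class QpcrResult:
    """ddCt quantification of one assay for one contrast."""

    assay: str
    delta_ct: pd.Series  # per-sample Ct_target - Ct_reference
    ddct: float  # mean dCt(case) - mean dCt(control)
    log2_fold_change: float  # -ddCt
    p: float  # Welch's t on per-sample dCt

    @property
    def fold_change(self) -> float:
        return 2.0**self.log2_fold_change


def ddct_fold_change(
    ct: pd.DataFrame,
    sample_groups: Mapping[str, str],
    contrast: tuple[str, str],
    reference_assay: str = "U6",
) -> dict[str, QpcrResult]:
    """ddCt relative quantification against a reference (housekeeping) assay.

    ``ct`` is tidy with columns ``sample``, ``assay``, ``ct`` (or a wide
    sample x assay table). dCt = Ct_target - Ct_reference per sample;
    ddCt = mean dCt(case) - mean dCt(control); log2 fold change = -ddCt.
    The p-value is Welch's t on the per-sample dCt values.
    """
    if {"sample", "assay", "ct"} <= set(ct.columns):
        wide = ct.pivot(index="sample", columns="assay", values="ct")
    else:
        wide = ct
    if reference_assay not in wide.columns:
        raise DiffexpError(f"reference assay {reference_assay!r} missing from Ct table")
    if wide[reference_assay].isna().any():
        bad = list(wide.index[wide[reference_assay].isna()])
        raise DiffexpError(f"missing reference Ct for samples {bad}")
    case, control = contrast
    case_samples = [s for s in wide.index if sample_groups.get(s) == case]
    control_samples = [s for s in wide.index if sample_groups.get(s) == control]
    if not case_samples or not control_samples:
        raise DiffexpError(f"contrast {contrast} has an empty group in the Ct table")
    results: dict[str, QpcrResult] = {}
    for assay in wide.columns:
        dct = wide[assay] - wide[reference_assay]
        ddct = float(dct[case_samples].mean() - dct[control_samples].mean())
        if assay == reference_assay:
            p = 1.0
        else:
            _, _, p = welch_t(dct[case_samples], dct[control_samples])
        results[assay] = QpcrResult(
            assay=assay, delta_ct=dct, ddct=ddct, log2_fold_change=-ddct, p=p
        )
    return results
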