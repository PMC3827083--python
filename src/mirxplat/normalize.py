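"""Vendor-style normalization of miRNA expression matrices.

Two arms are modeled. The Affymetrix-style arm is quantile-normalized across
samples. The Agilent-style arm is scaled to the 75th-percentile signal per
array, negative background-corrected values are clamped to a small positive
floor, and the 20 technical replicate spots per miRNA are summarized as
per-sample medians. Every transform appends a provenance line (operation,
parameters, matrix shape) to the matrix log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean, rankdata


class NormalizationError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """A miRNA x sample signal matrix with per-sample metadata.

    ``values``: DataFrame, rows = miRNA names (or a (mirna, spot) MultiIndex
    at the spot level), columns = sample names. ``sample_meta``: DataFrame
    indexed by sample with columns ``group`` and ``platform``. ``stage`` is
    one of ``raw``, ``normalized``, ``summarized``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    stage: str = "raw"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.sample_meta.index):
            unknown = set(self.values.columns) - set(self.sample_meta.index)
            raise NormalizationError(f"samples without metadata: {sorted(unknown)}")

    def _logged(self, values: pd.DataFrame, stage: str, line: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            sample_meta=self.sample_meta,
            stage=stage,
            log=self.log + [f"{line} shape={values.shape}"],
        )

    def groups(self) -> dict[str, list[str]]:
        """Sample names per group label."""
        return {g: list(idx) for g, idx in self.sample_meta.groupby("group").groups.items()}


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the same signal distribution (row-wise mean of
    sorted columns); tied values receive the mean of their candidate values.

    Idempotent; after normalization all column sorted multisets are equal.
    """
    vals = m.values
    if vals.shape[1] < 2:
        raise NormalizationError("quantile normalization needs >= 2 samples")
    if vals.isna().any().any():
        raise NormalizationError("missing values in matrix")
    arr = vals.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # ties -> mean rank
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    res = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return m._logged(res, "normalized", "quantile_normalize")


def percentile_scale(m: ExpressionMatrix, q: float = 75.0) -> ExpressionMatrix:
    """Scale each sample so its q-th percentile equals the geometric mean of
    all samples' q-th percentiles (linear-interpolation percentile).

    Idempotent; the common level is the cross-array geometric mean so that
    the overall signal scale is preserved.
    """
    vals = m.values
    pct = np.percentile(vals.to_numpy(dtype=float), q, axis=0)
    if np.any(pct <= 0):
        bad = [c for c, p in zip(vals.columns, pct) if p <= 0]
        raise NormalizationError(f"non-positive {q}th percentile in samples {bad}")
    target = gmean(pct)
    res = vals * (target / pct)
    return m._logged(res, "normalized", f"percentile_scale(q={q})")


def clamp_negatives(m: ExpressionMatrix, floor: float = 0.01) -> ExpressionMatrix:
    """Replace non-positive signals by ``floor``.

    Zeros are clamped along with negatives: a zero signal would map to -inf
    under the log2 transform taken downstream.
    """
    n_clamped = int((m.values <= 0).sum().sum())
    res = m.values.mask(m.values <= 0, floor)
    return m._logged(res, m.stage, f"clamp_negatives(floor={floor}, n_clamped={n_clamped})")


def summarize_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate spots to per-miRNA, per-sample median signals.

    Expects a spot-level matrix with a (mirna, spot) MultiIndex. Even spot
    counts use the mean-of-middle-two median convention.
    """
    vals = m.values
    if not isinstance(vals.index, pd.MultiIndex) or vals.index.nlevels != 2:
        raise NormalizationError("spot-level matrix needs a (mirna, spot) MultiIndex")
    counts = vals.groupby(level=0).size()
    if (counts < 1).any():
        raise NormalizationError("miRNA with zero spots")
    res = vals.groupby(level=0, sort=False).median()
    return m._logged(
        res,
        "summarized",
        f"summarize_replicates(spots: min={int(counts.min())}, max={int(counts.max())})",
    )
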