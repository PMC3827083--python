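"""Synthetic two-platform miRNA expression data with known ground truth.

The generator emulates a four-group mouse study design (male/female x
wild-type/transgenic, n = 6 per group) measured by two microarray platforms
sharing one miRNA universe, plus a qPCR arm normalized to the U6 reference
assay:

* log2-normal signals: per-miRNA baseline + group effect + per-observation
  noise; planted effects act in transgenic groups, optionally restricted to
  one sex (interaction terms, so per-sex contrasts are meaningful);
* platform-specific detectability drawn from a logistic sensitivity in GC
  content (platform A, Affymetrix-like, is biased against low-GC miRNAs;
  platform B is broadly sensitive) — undetectable miRNAs fall to a background
  level and lose their group effect;
* platform B emits 20 technical replicate spots per miRNA with a fraction of
  negative background-over-signal values, produced by subtracting a simulated
  background, never by sign-flipping;
* qPCR Ct values follow Ct = intercept - log2(expression) + noise with a
  group-constant U6 reference, so on a noiseless table ddCt = -(planted
  log2 fold change).

All randomness flows from a single seed, split per stage, so identical seeds
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mirxplat.normalize import ExpressionMatrix

GROUPS = ("M_WT", "F_WT", "M_cRaf", "F_cRaf")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlatformBias:
    """Logistic detection sensitivity in GC percent.

    P(detectable) = 1 / (1 + exp(-slope * (gc - midpoint))). A positive slope
    with a midpoint inside the GC range penalizes low-GC miRNAs.
    """

    gc_midpoint: float
    gc_slope: float

    def p_detect(self, gc: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.gc_slope * (np.asarray(gc, dtype=float) - self.gc_midpoint)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated two-platform experiment."""

    n_mirnas: int = 200
    n_per_group: int = 6
    groups: tuple[str, ...] = GROUPS
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    #: miRNA name -> (log2 fold change in transgenic groups, sex restriction
    #: "M"/"F"/None)
    planted_effects: Mapping[str, tuple[float, str | None]] = field(default_factory=dict)
    noise_sd: float = 0.3
    #: miRNA name -> GC percent; generated ~N(45, 10) clipped to [15, 80]
    #: when not given (the GC distribution of mature mouse miRNAs).
    gc_assignments: Mapping[str, float] | None = None
    platform_bias_a: PlatformBias = PlatformBias(gc_midpoint=45.0, gc_slope=0.25)
    platform_bias_b: PlatformBias = PlatformBias(gc_midpoint=25.0, gc_slope=0.15)
    n_replicate_spots: int = 20
    negative_rate: float = 0.05
    spot_noise_sd: float = 0.1
    background_log2_level: float = 2.0
    qpcr_ct_intercept: float = 30.0
    qpcr_u6_ct: float = 20.0
    qpcr_noise_sd: float = 0.2
    qpcr_assays: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SimulationError("n_per_group must be >= 2")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if not 0.0 <= self.negative_rate <= 1.0:
            raise SimulationError("negative_rate must be in [0, 1]")

    def mirna_names(self) -> list[str]:
        return [f"sim-miR-{i + 1:04d}" for i in range(self.n_mirnas)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth of one simulation run."""

    true_log2fc: pd.DataFrame  # miRNA x contrast ("M", "F")
    detectable: pd.DataFrame  # miRNA x platform ("A", "B"), bool
    gc: pd.Series  # miRNA -> GC percent

    def planted(self, sex: str) -> set[str]:
        col = self.true_log2fc[sex]
        return set(col.index[col != 0.0])


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _effects(cfg: SimulationConfig, names: list[str]) -> pd.DataFrame:
    unknown = set(cfg.planted_effects) - set(names)
    if unknown:
        raise SimulationError(f"planted effect on unknown miRNA: {sorted(unknown)}")
    eff = pd.DataFrame(0.0, index=names, columns=["M", "F"])
    for name, (lfc, sex) in cfg.planted_effects.items():
        if sex is None:
            eff.loc[name, ["M", "F"]] = lfc
        elif sex in ("M", "F"):
            eff.loc[name, sex] = lfc
        else:
            raise SimulationError(f"{name}: sex restriction must be 'M', 'F' or None, got {sex!r}")
    return eff


def _sample_names(cfg: SimulationConfig) -> tuple[list[str], pd.DataFrame]:
    samples, meta = [], []
    for g in cfg.groups:
        for k in range(cfg.n_per_group):
            s = f"{g}_{k + 1}"
            samples.append(s)
            meta.append((s, g))
    meta_df = pd.DataFrame(meta, columns=["sample", "group"]).set_index("sample")
    return samples, meta_df


def _signal_log2(
    cfg: SimulationConfig,
    names: list[str],
    samples: list[str],
    meta: pd.DataFrame,
    baseline: np.ndarray,
    effects: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-(miRNA, sample) log2 expression: baseline + group effect + noise."""
    out = np.tile(baseline[:, None], (1, len(samples)))
    for j, s in enumerate(samples):
        group = meta.loc[s, "group"]
        sex = group.split("_")[0]
        if group.endswith("cRaf"):
            out[:, j] += effects[sex].to_numpy()
    out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return pd.DataFrame(out, index=names, columns=samples)


def simulate_two_platforms(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Simulate raw matrices for both platforms and the planted ground truth.

    Returns (platform A miRNA x sample matrix, platform B spot-level matrix
    with a (mirna, spot) MultiIndex, ground truth). Platform assignment of
    samples is recorded in each matrix's ``sample_meta``.
    """
    names = cfg.mirna_names()
    effects = _effects(cfg, names)
    rng_base, rng_gc, rng_det, rng_sig, rng_spot, rng_neg = _rngs(cfg.seed, 6)

    baseline = rng_base.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(names))
    if cfg.gc_assignments is not None:
        missing = set(names) - set(cfg.gc_assignments)
        if missing:
            raise SimulationError(f"gc_assignments missing for {len(missing)} miRNAs")
        gc = pd.Series({n: float(cfg.gc_assignments[n]) for n in names})[names]
    else:
        gc = pd.Series(np.clip(rng_gc.normal(45.0, 10.0, size=len(names)), 15.0, 80.0).round(), index=names)

    detect_a = rng_det.random(len(names)) < cfg.platform_bias_a.p_detect(gc.to_numpy())
    detect_b = rng_det.random(len(names)) < cfg.platform_bias_b.p_detect(gc.to_numpy())
    detectable = pd.DataFrame({"A": detect_a, "B": detect_b}, index=names)

    samples, meta = _sample_names(cfg)
    signal = _signal_log2(cfg, names, samples, meta, baseline, effects, rng_sig)

    def observed(flags: np.ndarray) -> pd.DataFrame:
        obs = signal.copy()
        obs.loc[~flags, :] = cfg.background_log2_level
        return obs

    # platform A: one value per miRNA x sample
    a_vals = np.power(2.0, observed(detect_a))
    meta_a = meta.assign(platform="A")
    mat_a = ExpressionMatrix(values=a_vals, sample_meta=meta_a, stage="raw",
                             log=[f"simulate_two_platforms(seed={cfg.seed}) platform=A shape={a_vals.shape}"])

    # platform B: replicate spots with background-corrected negatives
    b_log2 = observed(detect_b).to_numpy()
    n_spots = cfg.n_replicate_spots
    spot_log2 = (
        np.repeat(b_log2, n_spots, axis=0)
        + rng_spot.normal(0.0, cfg.spot_noise_sd, size=(len(names) * n_spots, len(samples)))
    )
    spot_linear = np.power(2.0, spot_log2)
    # a fraction of spots had background exceeding the signal; the
    # background-corrected value is signal - background < 0
    neg_mask = rng_neg.random(spot_linear.shape) < cfg.negative_rate
    background = spot_linear * (1.0 + rng_neg.exponential(1.0, size=spot_linear.shape))
    spot_linear = np.where(neg_mask, spot_linear - background, spot_linear)
    idx = pd.MultiIndex.from_product([names, range(1, n_spots + 1)], names=["mirna", "spot"])
    b_vals = pd.DataFrame(spot_linear, index=idx, columns=samples)
    meta_b = meta.assign(platform="B")
    mat_b = ExpressionMatrix(values=b_vals, sample_meta=meta_b, stage="raw",
                             log=[f"simulate_two_platforms(seed={cfg.seed}) platform=B shape={b_vals.shape}"])

    truth = GroundTruth(true_log2fc=effects, detectable=detectable, gc=gc)
    return mat_a, mat_b, truth


def simulate_qpcr(cfg: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate a qPCR Ct table (tidy: sample, group, assay, ct) with U6.

    Assays default to the planted miRNAs (or the first 8 miRNAs when nothing
    is planted). Ct = intercept - log2(expression) + noise; the U6 reference
    is constant across groups up to noise, so ddCt recovers -(planted log2FC).
    """
    names = list(truth.true_log2fc.index)
    if cfg.qpcr_assays is not None:
        assays = list(cfg.qpcr_assays)
        unknown = set(assays) - set(names)
        if unknown:
            raise SimulationError(f"qPCR assay for unknown miRNA: {sorted(unknown)}")
    else:
        assays = sorted(cfg.planted_effects) or names[:8]
    samples, meta = _sample_names(cfg)
    (rng,) = _rngs(cfg.seed + 1_000_003, 1)

    rows = []
    for s in samples:
        group = meta.loc[s, "group"]
        sex = group.split("_")[0]
        transgenic = group.endswith("cRaf")
        for assay in assays:
            expr = cfg.baseline_log2_mean
            if transgenic:
                expr += float(truth.true_log2fc.loc[assay, sex])
            ct = cfg.qpcr_ct_intercept - expr + rng.normal(0.0, cfg.qpcr_noise_sd)
            rows.append((s, group, assay, ct))
        rows.append((s, group, "U6", cfg.qpcr_u6_ct + rng.normal(0.0, cfg.qpcr_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "group", "assay", "ct"])
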