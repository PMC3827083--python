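"""Detection calling, cross-platform overlap accounting, and the GC-bias
discordance diagnostic.

Two platforms sharing a feature universe ("overlapping genes") each call a
subset of miRNAs detected per sample group; the overlap summary reports the
per-platform detected fractions of the universe, the commonly detected
fraction, and the platform-exclusive sets. The GC diagnostic compares the GC
content of platform-exclusive vs shared significant miRNAs, the structure of
the argument that a GC-sensitive platform preferentially misses low-GC
miRNAs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Collection, Mapping

import numpy as np
import pandas as pd

from mirxplat.normalize import ExpressionMatrix


class ConcordanceError(ValueError):
    pass


@dataclass
class DetectionCall:
    """Per-group detected feature sets for one platform."""

    detected: pd.DataFrame  # bool, miRNA x group
    rule: str
    statistic: pd.DataFrame  # the per-group statistic the rule thresholded

    def detected_in(self, group: str) -> set[str]:
        return set(self.detected.index[self.detected[group]])

    def detected_any(self) -> set[str]:
        return set(self.detected.index[self.detected.any(axis=1)])


def call_detected(
    m: ExpressionMatrix,
    rule: str = "median_above_threshold",
    threshold: float | None = None,
) -> DetectionCall:
    """Call a miRNA detected in a group when its median signal across the
    group's samples exceeds a threshold (default: the matrix-wide median).

    The vendor present/absent flags behind published detection counts are
    proprietary; this rule is the package's reproducible stand-in, and an
    externally supplied flag matrix can be used instead via ``rule='external'``
    semantics at the pipeline level.
    """
    if rule != "median_above_threshold":
        raise ConcordanceError(f"unknown detection rule {rule!r}")
    if threshold is None:
        threshold = float(np.median(m.values.to_numpy()))
    med = pd.DataFrame(
        {g: m.values[samples].median(axis=1) for g, samples in m.groups().items()}
    )
    return DetectionCall(
        detected=med > threshold,
        rule=f"{rule}(threshold={threshold:.6g})",
        statistic=med,
    )


@dataclass
class ConcordanceSummary:
    """Detection overlap of two platforms against a shared universe."""

    universe_size: int
    detected_a: set[str]
    detected_b: set[str]
    common: set[str] = field(init=False)
    only_a: set[str] = field(init=False)
    only_b: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.common = self.detected_a & self.detected_b
        self.only_a = self.detected_a - self.detected_b
        self.only_b = self.detected_b - self.detected_a

    @property
    def fraction_a(self) -> float:
        return len(self.detected_a) / self.universe_size

    @property
    def fraction_b(self) -> float:
        return len(self.detected_b) / self.universe_size

    @property
    def fraction_common(self) -> float:
        return len(self.common) / self.universe_size

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "n_detected_a": len(self.detected_a),
            "n_detected_b": len(self.detected_b),
            "n_common": len(self.common),
            "n_only_a": len(self.only_a),
            "n_only_b": len(self.only_b),
            "fraction_a": self.fraction_a,
            "fraction_b": self.fraction_b,
            "fraction_common": self.fraction_common,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def overlap_stats(
    calls_a: Collection[str], calls_b: Collection[str], universe: Collection[str]
) -> ConcordanceSummary:
    """Overlap counts and fractions of two detected sets within a universe."""
    universe = set(universe)
    if not universe:
        raise ConcordanceError("empty universe")
    a, b = set(calls_a), set(calls_b)
    outside = (a | b) - universe
    if outside:
        raise ConcordanceError(f"calls outside the universe: {sorted(outside)[:5]}")
    return ConcordanceSummary(universe_size=len(universe), detected_a=a, detected_b=b)


@dataclass(frozen=True)
class GCGroupReport:
    members: tuple[str, ...]
    gc_values: tuple[float, ...]

    @property
    def gc_range(self) -> tuple[float, float] | None:
        return (min(self.gc_values), max(self.gc_values)) if self.gc_values else None

    @property
    def gc_mean(self) -> float | None:
        return float(np.mean(self.gc_values)) if self.gc_values else None


@dataclass(frozen=True)
class GCDiscordanceReport:
    only_a: GCGroupReport
    only_b: GCGroupReport
    shared: GCGroupReport

    def to_dict(self) -> dict:
        def block(r: GCGroupReport) -> dict:
            return {
                "members": list(r.members),
                "gc_values": list(r.gc_values),
                "gc_range": list(r.gc_range) if r.gc_range else None,
                "gc_mean": r.gc_mean,
            }

        return {"only_a": block(self.only_a), "only_b": block(self.only_b), "shared": block(self.shared)}


def gc_discordance(
    de_a: Collection[str], de_b: Collection[str], gc: Mapping[str, float]
) -> GCDiscordanceReport:
    """Compare GC content of platform-exclusive vs shared significant miRNAs.

    ``de_a`` / ``de_b`` are the significant sets from the two platforms; ``gc``
    maps miRNA name to GC percent. Missing GC for any named miRNA is an error.
    """
    a, b = set(de_a), set(de_b)
    missing = sorted(n for n in a | b if n not in gc)
    if missing:
        raise ConcordanceError(f"GC content missing for {missing}")

    def report(names: set[str]) -> GCGroupReport:
        ordered = tuple(sorted(names))
        return GCGroupReport(members=ordered, gc_values=tuple(gc[n] for n in ordered))

    return GCDiscordanceReport(
        only_a=report(a - b), only_b=report(b - a), shared=report(a & b)
    )
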