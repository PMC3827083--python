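"""Nearest-neighbor thermodynamics of RNA/DNA hybrid duplexes.

A microarray probe (DNA) hybridizes a mature miRNA (RNA). Duplex stability is
modeled as a sum of dinucleotide-step enthalpies/entropies/free energies plus
a helix-initiation term, using the RNA/DNA hybrid parameter set of Sugimoto
et al. (1995), shipped as a plain-text table and keyed by the RNA strand read
5'->3'.

Melting temperature follows the two-state formula with salt and formamide
corrections::

    Tm(degC) = 1000*dH / (dS + A + R*ln(Ct/4)) - 273.15
               + 16.6*log10([Na+]) - F*formamide_pct

with dH in kcal/mol and dS in cal/(K*mol) summed over steps *including* the
initiation enthalpy/entropy, A the helix initiation factor (an additional
entropic term in the denominator), Ct the oligonucleotide concentration in
mol/L, and F the Tm depression per percent formamide. Including the
parameter-table initiation dH/dS alongside A is the calibration that
reproduces the reference probe-panel Tm values; the per-step-only variant is
available via ``include_init_in_tm=False`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from mirxplat.seqlib import ProbeRecord, SequenceRecord, reverse_complement

RNA_STEPS = tuple(a + b for a in "ACGU" for b in "ACGU")


class ThermoError(ValueError):
    """Raised for mismatched duplexes, missing parameters or unphysical input."""


@dataclass(frozen=True)
class NearestNeighborTable:
    """Per-dinucleotide (dH, dS, dG37) parameters plus an initiation entry.

    dH and dG37 in kcal/mol, dS in cal/(K*mol). Steps are keyed by the RNA
    strand 5'->3'; the DNA strand is implied by complementarity.
    """

    steps: dict[str, tuple[float, float, float]]
    initiation: tuple[float, float, float]

    def __post_init__(self) -> None:
        missing = set(RNA_STEPS) - set(self.steps)
        extra = set(self.steps) - set(RNA_STEPS)
        if missing or extra:
            raise ThermoError(f"parameter table must have exactly the 16 RNA steps; missing={sorted(missing)} extra={sorted(extra)}")
        for key, (dh, ds, dg) in list(self.steps.items()) + [("INIT", self.initiation)]:
            recomputed = dh - 310.15 * ds / 1000.0
            if abs(recomputed - dg) > 0.1:
                raise ThermoError(
                    f"inconsistent entry {key}: dG37 {dg} vs dH - T*dS = {recomputed:.3f} kcal/mol"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NearestNeighborTable":
        steps: dict[str, tuple[float, float, float]] = {}
        init: tuple[float, float, float] | None = None
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    if line.split("\t") != ["step", "dH_kcal", "dS_cal", "dG37_kcal"]:
                        raise ThermoError(f"{path}: unexpected header {line!r}")
                    header_seen = True
                    continue
                key, dh, ds, dg = line.split("\t")
                entry = (float(dh), float(ds), float(dg))
                if key == "INIT":
                    init = entry
                else:
                    steps[key] = entry
        if init is None:
            raise ThermoError(f"{path}: missing INIT row")
        return cls(steps=steps, initiation=init)

    @classmethod
    def default(cls) -> "NearestNeighborTable":
        """The packaged Sugimoto RNA/DNA hybrid parameter set."""
        from importlib.resources import files

        return cls.from_tsv(str(files("mirxplat.data").joinpath("sugimoto_rna_dna_nn.tsv")))


@dataclass(frozen=True)
class ThermoConditions:
    """Hybridization conditions for the Tm formula.

    Defaults are the reference conditions of the probe panel: 1 M Na+, 100 uM
    oligonucleotide, helix initiation factor A = -10.8 cal/(K*mol), 35%
    formamide depressing Tm by 0.63 degC per percent.
    """

    na_molar: float = 1.0
    ct_molar: float = 1e-4
    a_init: float = -10.8
    f_formamide: float = 0.63
    formamide_pct: float = 35.0
    r_gas: float = 1.987


@dataclass(frozen=True)
class ThermoResult:
    """Duplex free energy at 37 degC, enthalpy, entropy, and melting temperature."""

    dG37: float
    dH: float
    dS: float
    tm: float
    n_steps: int
    probe_seq: str


@dataclass(frozen=True)
class Duplex:
    """An aligned RNA/DNA duplex as the list of RNA-strand dinucleotide steps.

    ``rna_start`` is the 0-based position on the miRNA where pairing begins;
    pairing always extends to the miRNA 3' end (3'-anchored probes) or covers
    the full length.
    """

    rna_name: str
    probe_name: str
    steps: tuple[str, ...]
    rna_start: int
    paired_length: int
    probe_seq: str


def pair_probe(rna: SequenceRecord, probe: ProbeRecord | SequenceRecord, include_tail: bool = True) -> Duplex:
    """Align a DNA probe to a mature miRNA as a contiguous 3'-anchored duplex.

    The probe must be the exact reverse complement of a 3'-anchored (or
    full-length) segment of the miRNA; any mismatch raises :class:`ThermoError`
    naming the first mismatched miRNA position.
    """
    if rna.alphabet != "RNA":
        raise ThermoError(f"{rna.name!r}: target must be RNA")
    if isinstance(probe, ProbeRecord):
        probe_rec = probe.with_tail() if include_tail else probe.without_tail()
    else:
        probe_rec = probe
    if probe_rec.alphabet != "DNA":
        raise ThermoError(f"{probe_rec.name!r}: probe must be DNA")
    if len(probe_rec) < 2:
        raise ThermoError(f"{probe_rec.name!r}: probe too short for a nearest-neighbor step")
    if len(probe_rec) > len(rna):
        raise ThermoError(
            f"{probe_rec.name!r}: probe ({len(probe_rec)} nt) longer than target {rna.name!r} ({len(rna)} nt)"
        )
    # The probe read 5'->3' pairs the miRNA 3'->5'; its reverse complement in
    # RNA space is the miRNA segment read 5'->3', which must sit at the 3' end.
    segment = reverse_complement(probe_rec, "RNA").seq
    start = len(rna) - len(segment)
    target = rna.seq[start:]
    for i, (a, b) in enumerate(zip(target, segment)):
        if a != b:
            raise ThermoError(
                f"probe {probe_rec.name!r} mismatches {rna.name!r} at miRNA position "
                f"{start + i + 1} ({a} vs probe-implied {b})"
            )
    steps = tuple(target[i : i + 2] for i in range(len(target) - 1))
    return Duplex(
        rna_name=rna.name,
        probe_name=probe_rec.name,
        steps=steps,
        rna_start=start,
        paired_length=len(segment),
        probe_seq=probe_rec.seq,
    )


def hybrid_delta_g(duplex: Duplex, nn: NearestNeighborTable | None = None) -> float:
    """Duplex free energy at 37 degC: per-step dG37 plus initiation, kcal/mol."""
    nn = nn or NearestNeighborTable.default()
    if not duplex.steps:
        raise ThermoError("duplex has no nearest-neighbor steps")
    try:
        dg = sum(nn.steps[s][2] for s in duplex.steps)
    except KeyError as exc:
        raise ThermoError(f"step {exc.args[0]!r} absent from parameter table") from exc
    return dg + nn.initiation[2]


def _enthalpy_entropy(duplex: Duplex, nn: NearestNeighborTable, include_init: bool) -> tuple[float, float]:
    try:
        dh = sum(nn.steps[s][0] for s in duplex.steps)
        ds = sum(nn.steps[s][1] for s in duplex.steps)
    except KeyError as exc:
        raise ThermoError(f"step {exc.args[0]!r} absent from parameter table") from exc
    if include_init:
        dh += nn.initiation[0]
        ds += nn.initiation[1]
    return dh, ds


def hybrid_tm(
    duplex: Duplex,
    nn: NearestNeighborTable | None = None,
    cond: ThermoConditions | None = None,
    include_init_in_tm: bool = True,
) -> float:
    """Two-state melting temperature in degC with salt and formamide corrections."""
    nn = nn or NearestNeighborTable.default()
    cond = cond or ThermoConditions()
    if not duplex.steps:
        raise ThermoError("duplex has no nearest-neighbor steps")
    dh, ds = _enthalpy_entropy(duplex, nn, include_init_in_tm)
    denom = ds + cond.a_init + cond.r_gas * math.log(cond.ct_molar / 4.0)
    if denom >= 0:
        raise ThermoError(f"unphysical duplex: Tm denominator {denom:.3f} >= 0")
    tm_kelvin = 1000.0 * dh / denom
    return (
        tm_kelvin
        - 273.15
        + 16.6 * math.log10(cond.na_molar)
        - cond.f_formamide * cond.formamide_pct
    )


def thermo_result(
    rna: SequenceRecord,
    probe: SequenceRecord,
    nn: NearestNeighborTable | None = None,
    cond: ThermoConditions | None = None,
) -> ThermoResult:
    """ΔG37, ΔH, ΔS and Tm for one physical probe species."""
    nn = nn or NearestNeighborTable.default()
    cond = cond or ThermoConditions()
    duplex = pair_probe(rna, probe)
    dh, ds = _enthalpy_entropy(duplex, nn, include_init=True)
    return ThermoResult(
        dG37=hybrid_delta_g(duplex, nn),
        dH=dh,
        dS=ds,
        tm=hybrid_tm(duplex, nn, cond),
        n_steps=len(duplex.steps),
        probe_seq=probe.seq,
    )


def probe_variants(
    rna: SequenceRecord,
    probe: ProbeRecord,
    nn: NearestNeighborTable | None = None,
    cond: ThermoConditions | None = None,
) -> list[ThermoResult]:
    """Thermodynamics for each physical probe species.

    Probes with an optional 3' residue yield two results, the tail-bearing
    variant first (matching the parenthesized-first layout of vendor tables);
    plain probes yield one.
    """
    return [thermo_result(rna, variant, nn, cond) for variant in probe.variants()]
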