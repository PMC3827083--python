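"""Nucleotide sequence records, GC content, complementarity, and sequence IO.

The unit of analysis is a mature miRNA (RNA, 18-25 nt) or a microarray
detection probe (DNA). Probes on hairpin-linker platforms may carry a single
optional 3' residue, written ``CACAAACCATTATGTGCTGCT(A)`` in vendor tables;
:class:`ProbeRecord` models that explicitly.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

RNA_BASES = frozenset("ACGU")
DNA_BASES = frozenset("ACGT")

_COMPLEMENT = {
    # target alphabet decides T vs U on output
    "A": {"DNA": "T", "RNA": "U"},
    "C": {"DNA": "G", "RNA": "G"},
    "G": {"DNA": "C", "RNA": "C"},
    "T": {"DNA": "A", "RNA": "A"},
    "U": {"DNA": "A", "RNA": "A"},
}

Alphabet = Literal["RNA", "DNA"]


class SequenceError(ValueError):
    """Raised for empty, mixed-alphabet or otherwise invalid sequences."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with a declared alphabet.

    Input is uppercased on ingest. A ``T`` in an RNA-declared sequence is
    rejected rather than silently converted, and vice versa for ``U`` in DNA.
    """

    name: str
    seq: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise SequenceError(f"{self.name!r}: empty sequence")
        if self.alphabet not in ("RNA", "DNA"):
            raise SequenceError(f"{self.name!r}: unknown alphabet {self.alphabet!r}")
        allowed = RNA_BASES if self.alphabet == "RNA" else DNA_BASES
        bad = set(self.seq) - allowed
        if bad:
            raise SequenceError(
                f"{self.name!r}: illegal {self.alphabet} base(s) {sorted(bad)} in {self.seq!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProbeRecord:
    """A DNA detection probe with an optional single 3'-appended residue.

    Vendor tables write the optional residue in parentheses after the probe
    body. ``with_tail`` / ``without_tail`` return plain :class:`SequenceRecord`
    views of the two physical probe species.
    """

    base: SequenceRecord
    optional_tail: str | None = None

    def __post_init__(self) -> None:
        if self.base.alphabet != "DNA":
            raise SequenceError(f"{self.base.name!r}: probe must be DNA")
        if self.optional_tail is not None:
            tail = self.optional_tail.upper()
            if len(tail) != 1 or tail not in DNA_BASES:
                raise SequenceError(
                    f"{self.base.name!r}: optional tail must be a single DNA base, got {self.optional_tail!r}"
                )
            object.__setattr__(self, "optional_tail", tail)

    @classmethod
    def from_string(cls, name: str, text: str) -> "ProbeRecord":
        """Parse vendor notation like ``ACAACCAGCTAAGACACTG(C)``."""
        text = text.strip().upper()
        m = re.fullmatch(r"([ACGT]+)(?:\(([ACGT])\))?", text)
        if m is None:
            raise SequenceError(f"{name!r}: cannot parse probe string {text!r}")
        body, tail = m.group(1), m.group(2)
        return cls(base=SequenceRecord(name, body, "DNA"), optional_tail=tail)

    def without_tail(self) -> SequenceRecord:
        return self.base

    def with_tail(self) -> SequenceRecord:
        if self.optional_tail is None:
            return self.base
        return SequenceRecord(self.base.name, self.base.seq + self.optional_tail, "DNA")

    def variants(self) -> list[SequenceRecord]:
        """Physical probe species, tail-bearing variant first when present."""
        if self.optional_tail is None:
            return [self.base]
        return [self.with_tail(), self.without_tail()]

    def __str__(self) -> str:
        if self.optional_tail is None:
            return self.base.seq
        return f"{self.base.seq}({self.optional_tail})"


def gc_content(rec: SequenceRecord) -> int:
    """GC content as an integer percent, truncated toward zero.

    Truncation (``floor`` of the percentage) is the convention of the
    reference probe panel this package reproduces: 12/22 -> 54, not 55.
    """
    gc = sum(1 for b in rec.seq if b in "GC")
    return math.floor(100.0 * gc / len(rec.seq))


def gc_fraction(rec: SequenceRecord) -> float:
    """Unrounded GC fraction in [0, 1]."""
    return sum(1 for b in rec.seq if b in "GC") / len(rec.seq)


def reverse_complement(rec: SequenceRecord, out_alphabet: Alphabet | None = None) -> SequenceRecord:
    """Watson-Crick reverse complement, optionally crossing alphabets.

    ``out_alphabet`` defaults to the input alphabet. U<->A pairing applies
    when crossing alphabets (the hybridization relation between a mature
    miRNA and its DNA probe).
    """
    out = out_alphabet or rec.alphabet
    if out not in ("RNA", "DNA"):
        raise SequenceError(f"unknown alphabet {out!r}")
    comp = "".join(_COMPLEMENT[b][out] for b in reversed(rec.seq))
    return SequenceRecord(rec.name, comp, out)


def _infer_alphabet(seq: str) -> Alphabet:
    has_u, has_t = "U" in seq, "T" in seq
    if has_u and has_t:
        raise SequenceError(f"sequence mixes T and U: {seq!r}")
    return "RNA" if has_u else "DNA"


def read_sequences(path: str | Path, format: str | None = None) -> list[SequenceRecord]:
    """Read FASTA or TSV (``name<TAB>sequence<TAB>alphabet``) sequence files.

    The format is inferred from the extension when not given. FASTA carries no
    alphabet column, so the alphabet is inferred per record (U => RNA,
    otherwise DNA); sequences mixing T and U are rejected.
    """
    path = Path(path)
    fmt = (format or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "fasta")).lower()
    records: list[SequenceRecord] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            records.append(SequenceRecord(rec.id, seq, _infer_alphabet(seq)))
        return records
    if fmt == "tsv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"name", "sequence", "alphabet"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise SequenceError(f"{path}: TSV header must contain {sorted(required)}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    records.append(
                        SequenceRecord(row["name"], row["sequence"], row["alphabet"].upper())
                    )
                except (SequenceError, KeyError, AttributeError) as exc:
                    raise SequenceError(f"{path}:{lineno}: {exc}") from exc
        return records
    raise SequenceError(f"unknown sequence format {fmt!r}")


def write_sequences(records: Iterable[SequenceRecord], path: str | Path, format: str | None = None) -> None:
    """Write records as FASTA or TSV; round-trips with :func:`read_sequences`."""
    path = Path(path)
    fmt = (format or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "fasta")).lower()
    records = list(records)
    if fmt == "fasta":
        bio = [_BioSeqRecord(Seq(r.seq), id=r.name, description="") for r in records]
        SeqIO.write(bio, str(path), "fasta")
    elif fmt == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["name", "sequence", "alphabet"])
            for r in records:
                writer.writerow([r.name, r.seq, r.alphabet])
    else:
        raise SequenceError(f"unknown sequence format {fmt!r}")


@dataclass(frozen=True)
class PanelEntry:
    """One assay of the packaged miRNA/probe panel."""

    mirna: SequenceRecord
    agilent_probe: ProbeRecord
    affymetrix_probe: ProbeRecord


def load_probe_panel(path: str | Path | None = None) -> list[PanelEntry]:
    """Load the packaged 12-assay miRNA/probe panel (or a user TSV like it)."""
    if path is None:
        from importlib.resources import files

        path = files("mirxplat.data").joinpath("mirna_probe_panel.tsv")
    entries = []
    with open(str(path), newline="") as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        entries.append(
            PanelEntry(
                mirna=SequenceRecord(row["name"], row["mirna_sequence"], "RNA"),
                agilent_probe=ProbeRecord.from_string(row["name"], row["agilent_probe"]),
                affymetrix_probe=ProbeRecord.from_string(row["name"], row["affymetrix_probe"]),
            )
        )
    return entries
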