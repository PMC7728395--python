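"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate conventions
----------------------
Everything inside the package is 0-based, half-open, plus-strand ordered.
BLAST tabular input is 1-based inclusive and may carry descending subject
coordinates on minus-strand hits; both quirks are normalized at read time
and never leak downstream.  BED output is half-open, matching the internal
convention directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Hsp",
    "GenomeInterval",
    "read_blast_tab",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_rate_table",
    "read_divergence_table",
    "read_overlap_matrix",
    "normalize_sequence",
]

_IUPAC_EXTRA = set("RYSWKMBDHVU")


@dataclass(frozen=True)
class GenomeInterval:
    """A located stretch of a contig: 0-based half-open, optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Hsp:
    """One normalized high-scoring segment pair from a homology search.

    ``percent_identity`` is a fraction in [0, 1]; subject coordinates are
    always ascending with the orientation recorded in ``strand``.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    percent_identity: float
    bit_score: float
    search_kind: str = "nucleotide"

    def __post_init__(self) -> None:
        if self.s_start >= self.s_end:
            raise ValueError("subject coordinates must be normalized ascending")
        if self.bit_score < 0:
            raise ValueError("bit_score must be non-negative")
        if not 0.0 <= self.percent_identity <= 1.0:
            raise ValueError("percent_identity must lie in [0, 1]")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def subject_interval(self) -> GenomeInterval:
        return GenomeInterval(self.subject_id, self.s_start, self.s_end, self.strand)


def _one_to_zero(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (coordinates already ascending)."""
    return start_1based - 1, end_1based


def read_blast_tab(path: str | Path, search_kind: str = "nucleotide") -> list[Hsp]:
    """Parse a 12-column tabular homology-hit file into normalized ``Hsp``s.

    Descending subject coordinates are flipped and the strand set to "-";
    the identity column (percent) is rescaled to a fraction.  Extra columns
    beyond the standard twelve are ignored.
    """
    if search_kind not in {"nucleotide", "translated"}:
        raise ValueError(f"unknown search_kind {search_kind!r}")
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                bit = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field ({exc})")
            strand = "+"
            if ss > se:
                ss, se = se, ss
                strand = "-"
            s0, s1 = _one_to_zero(ss, se)
            q0, q1 = _one_to_zero(min(qs, qe), max(qs, qe))
            hsps.append(
                Hsp(
                    query_id=qid,
                    subject_id=sid,
                    q_start=q0,
                    q_end=q1,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    percent_identity=pident / 100.0,
                    bit_score=bit,
                    search_kind=search_kind,
                )
            )
    return hsps


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into an ordered list of ``(id, sequence)`` pairs.

    Sequences are kept verbatim (case preserved); an empty file yields an
    empty list; duplicate ids raise.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    seen: dict[str, int] = {}
    dups = []
    for rid, _ in records:
        seen[rid] = seen.get(rid, 0) + 1
    dups = sorted(rid for rid, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path}: duplicate sequence ids: {', '.join(dups)}")
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 70
) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapping at ``wrap`` columns."""
    seqs = [SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqs)


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse non-ACGTN IUPAC codes to N (with a warning)."""
    up = seq.upper().replace("U", "T")
    extra = sorted(set(up) & _IUPAC_EXTRA)
    if extra:
        warnings.warn(
            f"ambiguous IUPAC codes {''.join(extra)} mapped to N", stacklevel=2
        )
        up = "".join("N" if c in _IUPAC_EXTRA else c for c in up)
    return up


def write_bed(intervals: Iterable[GenomeInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    """Write intervals as BED6 (name column optional, score fixed at 0)."""
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_rate_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (``taxon_pair_class``, ``r``) of synonymous rates.

    ``r`` is in substitutions per synonymous site per million years and must
    be strictly positive.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"taxon_pair_class", "r"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns taxon_pair_class, r")
    rates = dict(zip(df["taxon_pair_class"].astype(str), df["r"].astype(float)))
    bad = [k for k, v in rates.items() if not v > 0]
    if bad:
        raise ValueError(f"{path}: non-positive rate for {', '.join(bad)}")
    return rates


def read_divergence_table(path: str | Path) -> dict[frozenset, float]:
    """Read a species-pair divergence-time table (columns a, b, divergence_my)."""
    df = pd.read_csv(path, sep="\t")
    need = {"species_a", "species_b", "divergence_my"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out: dict[frozenset, float] = {}
    for _, row in df.iterrows():
        key = frozenset({str(row["species_a"]), str(row["species_b"])})
        out[key] = float(row["divergence_my"])
    return out


def read_overlap_matrix(path: str | Path) -> pd.DataFrame:
    """Read a binary species range-overlap matrix; must be symmetric with unit diagonal."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if list(df.columns) != list(df.index):
        raise ValueError(f"{path}: row and column species differ")
    for a in df.index:
        if df.loc[a, a] != 1:
            raise ValueError(f"{path}: diagonal entry for {a} is not 1")
        for b in df.columns:
            if df.loc[a, b] != df.loc[b, a]:
                raise ValueError(f"{path}: asymmetric entry ({a}, {b})")
            if df.loc[a, b] not in (0, 1):
                raise ValueError(f"{path}: non-binary entry ({a}, {b})")
    return df.astype(int)
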