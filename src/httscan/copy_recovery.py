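"""Reconstruction of full-length TE copies from fragmented homology hits.

A transposable-element insertion usually shows up in a homology search as
several high-scoring segment pairs (HSPs) broken by indels, nested
insertions or diverged internal regions.  Copies are rebuilt by keeping
hits with a bit-score strictly above a noise floor (default 200) and then
chaining hits of the same family, contig and strand whose genomic gap does
not exceed ``max_gap`` (default 1000 nt) into a single spanning interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from ._align import revcomp
from .io_formats import GenomeInterval, Hsp

__all__ = ["TeCopy", "filter_hsps", "merge_hsps", "extract_copy_sequences"]


@dataclass(frozen=True)
class TeCopy:
    """A reconstructed genomic TE copy in family orientation."""

    family_label: str
    location: GenomeInterval
    species: str = ""
    sequence: str = ""
    source_hsp_count: int = 1

    def __post_init__(self) -> None:
        if self.sequence and len(self.sequence) != len(self.location):
            raise ValueError("sequence length must equal interval length")
        if self.source_hsp_count < 1:
            raise ValueError("source_hsp_count must be >= 1")


def filter_hsps(hsps: list[Hsp], min_bit_score: float = 200.0) -> list[Hsp]:
    """Keep HSPs with bit-score strictly greater than ``min_bit_score``.

    The threshold is exclusive: a hit scoring exactly the floor is treated
    as a random hit and dropped.  Input order is preserved.
    """
    return [h for h in hsps if h.bit_score > min_bit_score]


def merge_hsps(hsps: list[Hsp], max_gap: int = 1000) -> list[TeCopy]:
    """Chain same-family, same-contig, same-strand HSPs into copy intervals.

    Within each (family, contig, strand) group, hits sorted by start are
    merged transitively whenever the gap to the previous merged block
    (``next.start - block.end``) is at most ``max_gap``; overlapping hits
    therefore always merge.  The result is independent of input order and
    idempotent, with surviving blocks separated by gaps > ``max_gap``.
    """
    def key(h: Hsp):
        return (h.query_id, h.subject_id, h.strand)

    copies: list[TeCopy] = []
    for (family, contig, strand), group in groupby(sorted(hsps, key=key), key=key):
        block_start = block_end = None
        n = 0
        for h in sorted(group, key=lambda h: (h.s_start, h.s_end)):
            if block_start is None:
                block_start, block_end, n = h.s_start, h.s_end, 1
            elif h.s_start - block_end <= max_gap:
                block_end = max(block_end, h.s_end)
                n += 1
            else:
                copies.append(
                    TeCopy(family, GenomeInterval(contig, block_start, block_end,
                                                  strand),
                           source_hsp_count=n)
                )
                block_start, block_end, n = h.s_start, h.s_end, 1
        if block_start is not None:
            copies.append(
                TeCopy(family, GenomeInterval(contig, block_start, block_end, strand),
                       source_hsp_count=n)
            )
    copies.sort(key=lambda c: (c.family_label, c.location.contig,
                               c.location.start, c.location.strand))
    return copies


def extract_copy_sequences(
    copies: list[TeCopy],
    genome: dict[str, str],
    species: str = "",
) -> list[TeCopy]:
    """Attach genomic sequence to copy intervals, reverse-complementing "-" copies.

    ``genome`` maps contig name to sequence.  Intervals outside contig
    bounds, or on missing contigs, raise with the offending contig named.
    """
    out: list[TeCopy] = []
    for copy in copies:
        loc = copy.location
        if loc.contig not in genome:
            raise KeyError(f"contig {loc.contig!r} absent from genome")
        contig_seq = genome[loc.contig]
        if loc.end > len(contig_seq):
            raise ValueError(
                f"interval [{loc.start}, {loc.end}) exceeds length "
                f"{len(contig_seq)} of contig {loc.contig!r}"
            )
        seq = contig_seq[loc.start:loc.end]
        if loc.strand == "-":
            seq = revcomp(seq)
        out.append(
            TeCopy(copy.family_label, loc, species=species or copy.species,
                   sequence=seq, source_hsp_count=copy.source_hsp_count)
        )
    return out
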