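"""Deterministic pairwise global alignment used across the package.

Scoring is fixed (match +1, mismatch -1, gap open -2, gap extend -1) so that
clustering, consensus building and flank comparison are reproducible without
an external aligner.  Identity is measured over the alignment columns between
the first and last column where both sequences carry a residue (terminal
gaps excluded); coverage is the fraction of the shorter sequence inside that
core region.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

__all__ = ["global_align", "identity_coverage", "revcomp"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@lru_cache(maxsize=1)
def _aligner(match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -2.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # end gaps are free: overhangs collect at the termini, where the
    # identity/coverage definitions exclude them
    aligner.end_gap_score = 0.0
    return aligner


def global_align(a: str, b: str) -> tuple[str, str]:
    """Return one optimal global alignment of ``a`` and ``b`` as gapped strings.

    Ties between co-optimal alignments are broken by taking the first
    alignment in Biopython's deterministic enumeration order.
    """
    a = a.upper()
    b = b.upper()
    if not a or not b:
        # degenerate: align against all-gap
        return a + "-" * len(b), "-" * len(a) + b
    alignment = next(iter(_aligner().align(a, b)))
    return str(alignment[0]), str(alignment[1])


def identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Global-alignment identity and mutual coverage for two sequences.

    Returns ``(identity, coverage)`` where identity = matches / core
    alignment columns (the region between the first and last column where
    both sequences carry a residue) and coverage = the smaller of the two
    sequences' fractions of residues lying inside that core.  Requiring
    mutual coverage keeps short fragments from attaching to full-length
    representatives they only partially span.
    """
    if not a or not b:
        return 0.0, 0.0
    ga, gb = global_align(a, b)
    both = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    if not both:
        return 0.0, 0.0
    lo, hi = both[0], both[-1] + 1
    core_a, core_b = ga[lo:hi], gb[lo:hi]
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    identity = matches / (hi - lo)
    cov_a = sum(1 for c in core_a if c != "-") / len(a)
    cov_b = sum(1 for c in core_b if c != "-") / len(b)
    return identity, min(cov_a, cov_b)
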