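"""Cross-species TE family construction and candidate filtering.

Copies are clustered greedily at 80% identity / 80% coverage (global
alignment, longest-first), a majority-rule consensus is built per cluster,
and families are screened with three rules before the horizontal-transfer
test: presence in at least two species, every member at least 600 nt, and
at least one member with an open reading frame longer than 300 aa (Class I)
or 200 aa (Class II).  ORFs are maximal stop-to-stop runs in any of the six
frames; no start codon is required because TE coding regions are routinely
5'-degraded in consensus sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import global_align, identity_coverage, revcomp
from .codon_stats import CODON_TO_AA

__all__ = [
    "Orf",
    "TeFamily",
    "cluster_sequences",
    "build_consensus",
    "find_longest_orf",
    "filter_htt_candidates",
    "trim_to_reference",
]

_TIE_ORDER = "ACGT"


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a (possibly reverse-complemented) sequence.

    ``start``/``end`` are 0-based half-open on the strand given; the stop
    codon is excluded, so ``aa_length == (end - start) / 3``.
    """

    start: int
    end: int
    frame: int
    strand: str
    aa_length: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.aa_length != (self.end - self.start) // 3:
            raise ValueError("aa_length inconsistent with coordinates")


@dataclass
class TeFamily:
    """A cross-species cluster of TE copies with its consensus."""

    family_id: str
    members: list  # list of (member_id, species, sequence)
    consensus: str = ""
    te_class: str = "unknown"
    reference_orf: tuple | None = None

    @property
    def species(self) -> set[str]:
        return {sp for _, sp, _ in self.members}


def cluster_sequences(
    records: list[tuple[str, str]],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
) -> list[list[tuple[str, str]]]:
    """Greedy incremental clustering at identity/coverage thresholds.

    Records are processed longest first (ties by id); each joins the
    best-identity existing cluster representative meeting both thresholds,
    or founds a new cluster.  The representative is the founding (longest)
    member, so the procedure is deterministic and order-independent after
    the canonical sort.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    reps: list[tuple[str, str]] = []
    clusters: list[list[tuple[str, str]]] = []
    for rec_id, seq in ordered:
        best = -1
        best_identity = 0.0
        for i, (_, rep_seq) in enumerate(reps):
            ident, cov = identity_coverage(seq, rep_seq)
            if ident >= min_identity and cov >= min_coverage:
                if ident > best_identity:
                    best, best_identity = i, ident
        if best >= 0:
            clusters[best].append((rec_id, seq))
        else:
            reps.append((rec_id, seq))
            clusters.append([(rec_id, seq)])
    return clusters


def build_consensus(cluster: list[tuple[str, str]]) -> str:
    """Majority-rule consensus from a star alignment against the longest member.

    Every member is globally aligned to the longest sequence; columns are
    the reference positions plus insertions observed in any pairwise
    alignment projected away (insertions relative to the reference are
    dropped).  Per column the strict-majority base wins, ties break by
    A < C < G < T, and columns where gaps hold the majority are removed.
    """
    if not cluster:
        raise ValueError("empty cluster")
    if len(cluster) == 1:
        return cluster[0][1].upper()
    ref_id, ref_seq = max(cluster, key=lambda r: (len(r[1]), r[0]))
    ref_seq = ref_seq.upper()
    # rows[i][j] = base of member i over reference position j ("-" if gapped)
    rows: list[list[str]] = []
    for mem_id, mem_seq in cluster:
        if mem_id == ref_id and mem_seq.upper() == ref_seq:
            rows.append(list(ref_seq))
            continue
        g_mem, g_ref = global_align(mem_seq.upper(), ref_seq)
        row = []
        for cm, cr in zip(g_mem, g_ref):
            if cr != "-":
                row.append(cm)
        rows.append(row)
    out = []
    for j in range(len(ref_seq)):
        column = [row[j] for row in rows]
        gaps = column.count("-")
        if gaps * 2 > len(column):
            continue
        best_base, best_count = "", -1
        for base in _TIE_ORDER + "N":
            c = column.count(base)
            if c > best_count:
                best_base, best_count = base, c
        out.append(best_base)
    return "".join(out)


def find_longest_orf(sequence: str) -> Orf:
    """Longest stop-to-stop open reading frame over all six frames.

    Runs are bounded by stop codons or the frame edges; the stop codon is
    excluded from the reported coordinates.  Ties are resolved in favour of
    the plus strand, then lower frame, then leftmost start.  Coordinates
    refer to the scanned strand (reverse-complement coordinates for "-").
    """
    seq = sequence.upper()
    best: Orf | None = None

    def consider(candidate: Orf) -> None:
        nonlocal best
        if best is None:
            best = candidate
            return
        key = (-candidate.aa_length, candidate.strand, candidate.frame,
               candidate.start)
        best_key = (-best.aa_length, best.strand, best.frame, best.start)
        if key < best_key:
            best = candidate

    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            run_start = frame
            pos = frame
            while pos + 3 <= len(s):
                codon = s[pos:pos + 3]
                is_stop = CODON_TO_AA.get(codon) == "*"
                if is_stop:
                    if pos > run_start:
                        consider(Orf(run_start, pos, frame, strand,
                                     (pos - run_start) // 3))
                    run_start = pos + 3
                pos += 3
            if pos > run_start:
                consider(Orf(run_start, pos, frame, strand,
                             (pos - run_start) // 3))
    if best is None:
        return Orf(0, 0, 0, "+", 0)
    return best


_ORF_MIN_AA_DEFAULT = {"ClassI": 300, "ClassII": 200}


def filter_htt_candidates(
    families: list[TeFamily],
    min_len: int = 600,
    orf_min_aa: dict[str, int] | None = None,
    min_species: int = 2,
) -> tuple[list[TeFamily], list[tuple[TeFamily, str]]]:
    """Apply the three candidate rules; reject with the first failing rule.

    Rule 1: members from at least ``min_species`` species.  Rule 2: every
    member at least ``min_len`` nt.  Rule 3: at least one member whose
    longest ORF is strictly longer than the class threshold (300 aa for
    Class I, 200 aa for Class II).  Families of unknown class raise unless
    ``orf_min_aa`` supplies an "unknown" threshold.
    """
    thresholds = dict(_ORF_MIN_AA_DEFAULT)
    if orf_min_aa:
        thresholds.update(orf_min_aa)
    kept: list[TeFamily] = []
    rejected: list[tuple[TeFamily, str]] = []
    for fam in families:
        if len(fam.species) < min_species:
            rejected.append((fam, f"present in fewer than {min_species} species"))
            continue
        short = [mid for mid, _, seq in fam.members if len(seq) < min_len]
        if short:
            rejected.append(
                (fam, f"member(s) shorter than {min_len} nt: {', '.join(short)}")
            )
            continue
        if fam.te_class not in thresholds:
            raise ValueError(
                f"family {fam.family_id}: no ORF threshold for class "
                f"{fam.te_class!r}"
            )
        min_aa = thresholds[fam.te_class]
        longest = max(
            (find_longest_orf(seq) for _, _, seq in fam.members),
            key=lambda o: o.aa_length,
        )
        if longest.aa_length <= min_aa:
            rejected.append(
                (fam, f"longest ORF {longest.aa_length} aa not greater than "
                      f"{min_aa} aa")
            )
            continue
        kept.append(fam)
    return kept, rejected


def trim_to_reference(
    alignment: list[tuple[str, str]], reference_id: str
) -> list[tuple[str, str]]:
    """Trim alignment columns outside the reference's aligned extent.

    Columns before the reference's first non-gap character and after its
    last are removed; trailing columns are then dropped until the number of
    reference residues retained is a multiple of three, keeping the result
    in the reference reading frame.
    """
    ref = dict(alignment).get(reference_id)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    residues = [i for i, c in enumerate(ref) if c != "-"]
    if not residues:
        raise ValueError(f"reference {reference_id!r} is all gaps")
    lo, hi = residues[0], residues[-1] + 1
    n_res = len([i for i in residues if lo <= i < hi])
    while n_res % 3 != 0:
        hi -= 1
        if ref[hi] != "-":
            n_res -= 1
    return [(rid, seq[lo:hi]) for rid, seq in alignment]
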