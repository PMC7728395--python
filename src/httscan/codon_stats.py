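"""Codon-level divergence and usage statistics.

Three quantities drive the whole inference:

* ``ds_ng86`` — synonymous divergence (dS) between two in-frame coding
  sequences by Nei & Gojobori site counting: synonymous sites are counted
  fractionally per codon, multi-substitution codons are averaged over all
  shortest mutational pathways (pathways through stop codons excluded),
  and the raw proportion pS is corrected for multiple hits with the
  Jukes–Cantor formula dS = -3/4 ln(1 - 4/3 pS).
* ``enc`` — Wright's effective number of codons (Nc), the codon-usage-bias
  index: Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk is the mean codon
  homozygosity of amino acids with k synonymous codons.  Nc runs from 20
  (one codon per amino acid, maximal bias) to 61 (uniform usage).
* ``k2p`` — the Kimura two-parameter distance separating transition (p)
  and transversion (q) proportions, K = -1/2 ln((1-2p-q) sqrt(1-2q)),
  used to date TE copies against their family consensus within a genome.

All functions apply pairwise deletion: alignment columns or codons
containing gaps, N, or stop codons are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

from ._align import global_align

__all__ = [
    "PairwiseDivergence",
    "CodonUsageStat",
    "K2pResult",
    "ds_ng86",
    "enc",
    "k2p",
    "family_k2p_profile",
    "CODON_TO_AA",
    "GENETIC_CODE_DEGENERACY",
]

_BASES = "ACGT"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> single-letter amino acid, "*" for stop (standard genetic code)
CODON_TO_AA: dict[str, str] = {
    c: _TABLE.forward_table.get(c, "*") for c in _CODONS
}

_AA_FAMILY: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    if _aa != "*":
        _AA_FAMILY.setdefault(_aa, []).append(_c)
#: amino acid -> number of synonymous codons (degeneracy class)
GENETIC_CODE_DEGENERACY: dict[str, int] = {
    aa: len(cods) for aa, cods in _AA_FAMILY.items()
}

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _codon_index(codon: str) -> int:
    """Codon -> 0..63, or -1 for anything containing a non-ACGT character."""
    idx = 0
    for ch in codon:
        pos = _BASES.find(ch)
        if pos < 0:
            return -1
        idx = idx * 4 + pos
    return idx


def _syn_fraction(codon: str) -> float:
    """Fractional count of synonymous sites in one codon (NG86).

    For each position, the fraction of the three possible single-nucleotide
    changes that preserve the amino acid; changes creating a stop codon
    count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODON_TO_AA[mutant] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous difference counts between two codons.

    Averages over all orderings of the differing positions; pathways whose
    intermediate codons are stops are discarded (unless every pathway is,
    in which case all are used).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathway_sd_nd: list[tuple[float, float]] = []
    all_sd_nd: list[tuple[float, float]] = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TO_AA[nxt] == "*" and step < len(order) - 1:
                through_stop = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur] and CODON_TO_AA[nxt] != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        all_sd_nd.append((sd, nd))
        if not through_stop:
            pathway_sd_nd.append((sd, nd))
    use = pathway_sd_nd or all_sd_nd
    sd = sum(x for x, _ in use) / len(use)
    nd = sum(y for _, y in use) / len(use)
    return sd, nd


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    syn_sites = np.zeros(64)
    stop = np.zeros(64, dtype=bool)
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c in enumerate(_CODONS):
        if CODON_TO_AA[c] == "*":
            stop[i] = True
        else:
            syn_sites[i] = _syn_fraction(c)
    for i, c1 in enumerate(_CODONS):
        if stop[i]:
            continue
        for j, c2 in enumerate(_CODONS):
            if stop[j] or j < i:
                continue
            s, n = _pathway_counts(c1, c2)
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = n
    return syn_sites, stop, sd, nd


_SYN_SITES, _STOP, _SD, _ND = _build_tables()


@dataclass(frozen=True)
class PairwiseDivergence:
    """NG86 site and difference counts plus Jukes–Cantor-corrected rates."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    n_codons: int
    saturated: bool = False


_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def encode_codons(seq: str) -> np.ndarray:
    """Encode a nucleotide string as codon indices (-1 for unusable codons)."""
    n = len(seq) // 3
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[: 3 * n]
    bases = _BASE_LUT[raw].reshape(n, 3)
    idx = bases[:, 0] * 16 + bases[:, 1] * 4 + bases[:, 2]
    idx[(bases < 0).any(axis=1)] = -1
    return idx


def ds_ng86(seq1: str, seq2: str) -> PairwiseDivergence:
    """Nei–Gojobori synonymous/nonsynonymous divergence between two sequences.

    Sequences must be equal length and in frame; codons containing gaps, N,
    or a stop in either sequence are skipped pairwise.  dS is flagged
    saturated (NaN) when pS >= 3/4.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be equal length")
    a = encode_codons(seq1)
    b = encode_codons(seq2)
    ok = (a >= 0) & (b >= 0)
    ok[ok] &= ~(_STOP[a[ok]] | _STOP[b[ok]])
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("no comparable codons")
    S = float((_SYN_SITES[a].sum() + _SYN_SITES[b].sum()) / 2.0)
    N = 3.0 * a.size - S
    Sd = float(_SD[a, b].sum())
    Nd = float(_ND[a, b].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    def jc(p: float) -> float:
        if p >= 0.75:
            return math.nan
        return -0.75 * math.log1p(-4.0 * p / 3.0)

    dS = jc(pS)
    dN = jc(pN)
    return PairwiseDivergence(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
        n_codons=int(a.size), saturated=math.isnan(dS),
    )


@dataclass(frozen=True)
class CodonUsageStat:
    """Effective number of codons with the per-class homozygosities behind it."""

    Nc: float
    n_codons: int
    class_homozygosity: dict[int, float]

    def __post_init__(self) -> None:
        if not 20.0 <= self.Nc <= 61.0:
            raise ValueError("Nc outside [20, 61]")


# degeneracy class -> number of amino acids in it (standard code)
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}

_FAMILY_IDX: dict[str, np.ndarray] = {
    aa: np.array([_codon_index(c) for c in cods], dtype=np.int64)
    for aa, cods in _AA_FAMILY.items()
}


def enc(sequence: str) -> CodonUsageStat:
    """Wright's effective number of codons for one in-frame coding sequence.

    Per amino acid observed >= 2 times, codon homozygosity is
    F = (n * sum(p_i^2) - 1) / (n - 1); class means are taken over amino
    acids of equal degeneracy.  A missing 3-fold class is imputed as
    (F2 + F4) / 2; any other missing class is imputed by assuming the same
    relative usage flatness as the observed classes.  The result is clipped
    to [20, 61].
    """
    codons = encode_codons(sequence)
    codons = codons[(codons >= 0)]
    codons = codons[~_STOP[codons]]
    if codons.size < 1:
        raise ValueError("sequence contains no usable codons")
    counts = np.bincount(codons, minlength=64)

    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam_idx in _FAMILY_IDX.items():
        k = fam_idx.size
        if k == 1:
            continue
        fam_counts = counts[fam_idx]
        n_aa = int(fam_counts.sum())
        if n_aa < 2:
            continue
        p2 = float(((fam_counts / n_aa) ** 2).sum())
        f_hat = (n_aa * p2 - 1.0) / (n_aa - 1.0)
        if f_hat > 0:
            f_by_class[k].append(f_hat)

    fbar: dict[int, float] = {
        k: float(np.mean(v)) for k, v in f_by_class.items() if v
    }
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    available = {k: v for k, v in fbar.items()}
    if not available:
        raise ValueError("too few codons to estimate any homozygosity class")
    # impute remaining classes on the k*F scale (k*F == 1 under uniform usage)
    mean_kf = float(np.mean([k * v for k, v in available.items()]))
    for k in _CLASS_SIZES:
        if k not in fbar:
            fbar[k] = min(1.0, mean_kf / k)

    nc = 2.0 + sum(_CLASS_SIZES[k] / fbar[k] for k in _CLASS_SIZES)
    nc = float(min(61.0, max(20.0, nc)))
    return CodonUsageStat(Nc=nc, n_codons=int(codons.size),
                          class_homozygosity=fbar)


@dataclass(frozen=True)
class K2pResult:
    """Transition/transversion proportions and the K2P distance."""

    p: float
    q: float
    K: float
    n_sites: int
    saturated: bool = False


def k2p(seq1: str, seq2: str) -> K2pResult:
    """Kimura two-parameter distance over ungapped, unambiguous columns."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be equal length")
    p_count = q_count = n = 0
    for x, y in zip(seq1.upper(), seq2.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in _TRANSITIONS:
                p_count += 1
            else:
                q_count += 1
    if n == 0:
        raise ValueError("no comparable sites")
    p = p_count / n
    q = q_count / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return K2pResult(p=p, q=q, K=math.nan, n_sites=n, saturated=True)
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2pResult(p=p, q=q, K=K, n_sites=n, saturated=False)


def family_k2p_profile(
    copies: list[tuple[str, str]], consensus: str
) -> dict:
    """Per-copy K2P distances to the family consensus, with mean and median.

    Each copy is globally aligned to the consensus before the distance is
    taken, so copies need not be pre-aligned.  The distribution of these
    distances is the family's intragenomic age profile: a recent burst
    piles copies near K = 0, an ancient one shifts the whole profile right.
    """
    if not copies:
        raise ValueError("no copies supplied")
    per_copy: list[tuple[str, float]] = []
    for copy_id, seq in copies:
        ga, gc = global_align(seq, consensus)
        res = k2p(ga, gc)
        if not res.saturated:
            per_copy.append((copy_id, res.K))
    if not per_copy:
        raise ValueError("no alignable (unsaturated) copies")
    values = np.array([v for _, v in per_copy])
    return {
        "per_copy": per_copy,
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "n": int(values.size),
    }
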