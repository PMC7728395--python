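"""Forward simulation of codon sequences with known inheritance histories.

The generator reproduces the statistical structure the transfer test
assumes, with complete ground truth:

* The amino-acid sequence is frozen; only synonymous substitutions occur,
  so alignments are trivially correct and dS is the only divergence axis.
* Each unit (gene or TE) carries a codon-bias parameter beta in [0, 1].
  The root sequence draws each amino acid's preferred codon with
  probability 1/k + beta (1 - 1/k) (k = degeneracy), giving an expected
  effective-number-of-codons Nc that falls from 61 (beta = 0) to 20
  (beta = 1).
* Along a branch of t million years each codon accrues
  Poisson(r_s * t * s_c) synonymous substitutions, where s_c is the
  codon's fractional synonymous site count and
  r_s = r_max * (1 - lambda_cub * b(beta)) with b(beta) the expected
  bias on a 0-1 scale, b = (61 - E[Nc | beta]) / 41.  Scaling the rate by
  the *expected* Nc (not the realized one) makes expected dS exactly
  linear in expected codon usage — the linear dS-CUB relation the
  regression assumes — while the realized Nc keeps natural sampling
  noise.  Substitutions resample among single-step synonymous neighbours
  weighted by the codon preference.
* A vertical TE evolves like a gene over the whole tree.  A horizontal TE
  evolves along the donor lineage; t_HT million years before the present
  its state is copied into the recipient, and both evolve independently
  to the tips, so donor-recipient divergence reflects 2 * t_HT rather
  than twice the species divergence.

Reproducibility: one root seed; every unit derives a child seed by CRC-32
hashing of its id, so adding units never perturbs existing ones.
"""

from __future__ import annotations

import json
import zlib
from functools import lru_cache
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .codon_stats import CODON_TO_AA, _CODONS, _SYN_SITES  # noqa: F401
from .io_formats import write_fasta

__all__ = [
    "TeSpec",
    "SimConfig",
    "SimTruth",
    "expected_enc",
    "synonymous_rate",
    "simulate_gene",
    "simulate_te",
    "simulate_copy_burst",
    "generate_study",
]

_BASES = "ACGT"

# ---- genetic-code machinery (preferred codons, synonymous neighbourhoods) --

_AA_FAMILY: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    if _aa != "*":
        _AA_FAMILY.setdefault(_aa, []).append(_c)
for _cods in _AA_FAMILY.values():
    _cods.sort()

_AAS = sorted(_AA_FAMILY)
#: one shared preferred codon per amino acid (alphabetically first)
PREFERRED = {aa: cods[0] for aa, cods in _AA_FAMILY.items()}

_IDX = {c: i for i, c in enumerate(_CODONS)}


def _single_step_syn_neighbors(codon: str) -> list[str]:
    out = []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if CODON_TO_AA[mut] == aa:
                out.append(mut)
    return out


_NEIGHBORS: list[np.ndarray] = [np.array([], dtype=np.int64)] * 64
_NEIGHBOR_PREF: list[np.ndarray] = [np.array([])] * 64
_DEGENERACY = np.zeros(64, dtype=np.int64)
for _c in _CODONS:
    if CODON_TO_AA[_c] == "*":
        continue
    nbs = _single_step_syn_neighbors(_c)
    _NEIGHBORS[_IDX[_c]] = np.array([_IDX[n] for n in nbs], dtype=np.int64)
    _NEIGHBOR_PREF[_IDX[_c]] = np.array(
        [1.0 if n == PREFERRED[CODON_TO_AA[n]] else 0.0 for n in nbs]
    )
    _DEGENERACY[_IDX[_c]] = len(_AA_FAMILY[CODON_TO_AA[_c]])

_NB_LIST: list[list[int]] = [list(a) for a in _NEIGHBORS]
_NB_PREF_LIST: list[list[bool]] = [[bool(x) for x in a] for a in _NEIGHBOR_PREF]


def _codon_probs(beta: float) -> dict[str, np.ndarray]:
    """Per amino acid, the codon sampling distribution at bias ``beta``."""
    probs = {}
    for aa, cods in _AA_FAMILY.items():
        k = len(cods)
        p = np.full(k, (1.0 - beta) / k)
        p[0] = 1.0 / k + beta * (1.0 - 1.0 / k)  # cods[0] is the preferred one
        probs[aa] = p / p.sum()
    return probs


def expected_enc(beta: float) -> float:
    """Expected Nc of the preference distribution itself (long-sequence limit)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    fbar = {}
    for k, n_aa in ((2, 9), (3, 1), (4, 5), (6, 3)):
        p_pref = 1.0 / k + beta * (1.0 - 1.0 / k)
        p_other = (1.0 - beta) / k
        fbar[k] = p_pref ** 2 + (k - 1) * p_other ** 2
    nc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return float(min(61.0, max(20.0, nc)))


def synonymous_rate(beta: float, r_max: float, lambda_cub: float) -> float:
    """Synonymous rate r_s = r_max (1 - lambda * b(beta)), b on a 0-1 scale."""
    b = (61.0 - expected_enc(beta)) / 41.0
    return r_max * (1.0 - lambda_cub * b)


@dataclass(frozen=True)
class TeSpec:
    """One TE to simulate: inheritance mode and, if horizontal, the event."""

    unit_id: str
    mode: str  # vertical | horizontal
    donor: str = ""
    recipient: str = ""
    t_ht_my: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in {"vertical", "horizontal"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "horizontal" and not (self.donor and self.recipient):
            raise ValueError("horizontal spec needs donor and recipient")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth record emitted with every simulated unit."""

    unit_id: str
    kind: str  # gene | te
    beta: float
    r_s: float
    mode: str = ""
    donor: str = ""
    recipient: str = ""
    t_ht_my: float = float("nan")
    branch_substitutions: tuple = ()


@dataclass
class SimConfig:
    """Study-level simulation settings (defaults mirror the analysed design:
    50 orthologous genes of 500 codons per species pair, 600-codon TEs)."""

    species_tree: str  # Newick, branch lengths in My
    n_genes: int = 50
    codons_per_gene: int = 500
    codons_per_te: int = 600
    r_max: float = 0.02
    lambda_cub: float = 0.5
    te_specs: list[TeSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_cub < 1.0:
            raise ValueError("lambda_cub must lie in [0, 1)")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


def unit_rng(seed: int, unit_id: str) -> np.random.Generator:
    """Child generator for one unit, stable under addition of other units."""
    return np.random.default_rng([seed, zlib.crc32(unit_id.encode())])


def _draw_root(n_codons: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Root codon-index sequence: uniform amino acids, biased codon choice."""
    probs = _codon_probs(beta)
    aas = rng.integers(len(_AAS), size=n_codons)
    out = np.empty(n_codons, dtype=np.int64)
    for ai, aa in enumerate(_AAS):
        mask = aas == ai
        n = int(mask.sum())
        if n == 0:
            continue
        fam_idx = np.array([_IDX[c] for c in _AA_FAMILY[aa]], dtype=np.int64)
        out[mask] = fam_idx[rng.choice(len(fam_idx), size=n, p=probs[aa])]
    return out


def _evolve(
    codons: np.ndarray, t_my: float, r_s: float, beta: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Evolve a codon-index array along one branch; returns (state, n_events)."""
    out = codons.copy()
    lam = r_s * t_my * _SYN_SITES[out]
    n_events = rng.poisson(lam)
    total = int(n_events.sum())
    # per-codon neighbour weights for this unit's preference strength
    weight_cache: dict[int, tuple[list[int], list[float], float]] = {}
    for pos in np.nonzero(n_events)[0]:
        for _ in range(n_events[pos]):
            cur = int(out[pos])
            cached = weight_cache.get(cur)
            if cached is None:
                nbs = _NB_LIST[cur]
                if not nbs:
                    weight_cache[cur] = ([], [], 0.0)
                    continue
                k = int(_DEGENERACY[cur])
                w = [
                    1.0 / k + beta * (1.0 - 1.0 / k) if pref else
                    (1.0 - beta) / k
                    for pref in _NB_PREF_LIST[cur]
                ]
                tot = sum(w)
                if tot == 0.0:  # beta == 1 on the preferred codon itself
                    w = [1.0] * len(nbs)
                    tot = float(len(nbs))
                cached = (nbs, w, tot)
                weight_cache[cur] = cached
            nbs, w, tot = cached
            if not nbs:
                continue
            r = rng.random() * tot
            acc = 0.0
            for j, wj in enumerate(w):
                acc += wj
                if r <= acc:
                    out[pos] = nbs[j]
                    break
    return out, total


def _to_string(codons: np.ndarray) -> str:
    return "".join(_CODONS[i] for i in codons)


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("species tree must have branch lengths (My)")
    return tree


@lru_cache(maxsize=32)
def _tree_cache(newick: str) -> dendropy.Tree:
    return _parse_tree(newick)


def _taxon(node: dendropy.Node) -> str:
    return node.taxon.label.replace(" ", "_")


def simulate_gene(
    beta: float,
    tree: dendropy.Tree | str,
    config: SimConfig,
    rng: np.random.Generator,
    n_codons: int | None = None,
    unit_id: str = "gene",
) -> tuple[dict[str, str], SimTruth]:
    """Simulate one unit over the whole tree; returns tip alignment + truth."""
    if isinstance(tree, str):
        tree = _tree_cache(tree)
    n_codons = n_codons or config.codons_per_gene
    r_s = synonymous_rate(beta, config.r_max, config.lambda_cub)
    root_state = _draw_root(n_codons, beta, rng)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_state}
    branch_subs = []
    tips: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = root_state
        else:
            parent_state = states[id(node.parent_node)]
            state, n_sub = _evolve(parent_state, node.edge.length, r_s, beta, rng)
            branch_subs.append(n_sub)
        states[id(node)] = state
        if node.is_leaf():
            tips[_taxon(node)] = _to_string(state)
    truth = SimTruth(
        unit_id=unit_id, kind="gene", beta=beta, r_s=r_s, mode="vertical",
        branch_substitutions=tuple(branch_subs),
    )
    return tips, truth


def simulate_te(
    spec: TeSpec,
    tree: dendropy.Tree | str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], SimTruth]:
    """Simulate one TE with a vertical or horizontal history.

    Vertical TEs follow the gene process over the whole tree.  Horizontal
    TEs evolve along the donor lineage only; at ``t_ht_my`` before the
    present the running state is copied into the recipient, after which
    donor and recipient copies evolve independently for ``t_ht_my``.
    """
    if isinstance(tree, str):
        tree = _tree_cache(tree)
    if spec.mode == "vertical":
        tips, truth = simulate_gene(
            spec.beta, tree, config, rng,
            n_codons=config.codons_per_te, unit_id=spec.unit_id,
        )
        return tips, SimTruth(
            unit_id=spec.unit_id, kind="te", beta=spec.beta, r_s=truth.r_s,
            mode="vertical", branch_substitutions=truth.branch_substitutions,
        )

    labels = {_taxon(leaf) for leaf in tree.leaf_node_iter()}
    for sp in (spec.donor, spec.recipient):
        if sp not in labels:
            raise ValueError(f"species {sp!r} not in tree")
    donor_leaf = next(
        leaf for leaf in tree.leaf_node_iter() if _taxon(leaf) == spec.donor
    )
    path = []
    node = donor_leaf
    while node.parent_node is not None:
        path.append(node.edge.length)
        node = node.parent_node
    path.reverse()
    depth = sum(path)
    if not 0.0 <= spec.t_ht_my < depth:
        raise ValueError("t_ht_my must lie within the donor root-to-tip depth")
    r_s = synonymous_rate(spec.beta, config.r_max, config.lambda_cub)
    state = _draw_root(config.codons_per_te, spec.beta, rng)
    # evolve down the donor lineage to the moment of transfer
    state, n_pre = _evolve(state, depth - spec.t_ht_my, r_s, spec.beta, rng)
    donor_state, n_d = _evolve(state, spec.t_ht_my, r_s, spec.beta, rng)
    recip_state, n_r = _evolve(state, spec.t_ht_my, r_s, spec.beta, rng)
    tips = {spec.donor: _to_string(donor_state),
            spec.recipient: _to_string(recip_state)}
    truth = SimTruth(
        unit_id=spec.unit_id, kind="te", beta=spec.beta, r_s=r_s,
        mode="horizontal", donor=spec.donor, recipient=spec.recipient,
        t_ht_my=spec.t_ht_my, branch_substitutions=(n_pre, n_d, n_r),
    )
    return tips, truth


def simulate_copy_burst(
    consensus: str,
    age_my: float,
    per_site_rate: float,
    n_copies: int,
    rng: np.random.Generator,
    kappa: float = 2.0,
) -> list[str]:
    """Intragenomic copy set from a single transposition burst of known age.

    Each copy receives Poisson(rate * age * L) substitutions at uniform
    positions with a kappa-fold transition bias, so the expected
    copy-to-consensus K2P distance is approximately rate * age.
    """
    if age_my < 0 or per_site_rate < 0:
        raise ValueError("age and rate must be non-negative")
    consensus = consensus.upper()
    length = len(consensus)
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    p_ts = kappa / (kappa + 2.0)
    copies = []
    for _ in range(n_copies):
        seq = list(consensus)
        for _ in range(rng.poisson(per_site_rate * age_my * length)):
            pos = int(rng.integers(length))
            base = seq[pos]
            if base not in transition:
                continue
            if rng.random() < p_ts:
                seq[pos] = transition[base]
            else:
                seq[pos] = transversions[base][int(rng.integers(2))]
        copies.append("".join(seq))
    return copies


def _pairwise_divergence_table(tree: dendropy.Tree) -> list[tuple[str, str, float]]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    rows = []
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1:]:
            half = pdm.distance(ta, tb) / 2.0
            rows.append((ta.label.replace(" ", "_"),
                         tb.label.replace(" ", "_"), half))
    return rows


def generate_study(config: SimConfig, outdir: str | Path) -> Path:
    """Emit a complete, deterministic study bundle under ``outdir``.

    Contents: ``tree.nwk``; ``genes/`` and ``tes/`` with one aligned FASTA
    per unit (records named by species); ``truth_genes.tsv`` /
    ``truth_tes.tsv``; ``divergence.tsv`` (pairwise split times in My);
    ``copies/`` with one burst copy set; a toy ``genome.fa`` + ``hits.tsv``
    pair exercising copy recovery; and ``sim_config.json`` echoing every
    setting.  Identical configs produce byte-identical bundles.
    """
    outdir = Path(outdir)
    tree = _parse_tree(config.species_tree)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    (outdir / "tes").mkdir(exist_ok=True)
    (outdir / "copies").mkdir(exist_ok=True)

    (outdir / "tree.nwk").write_text(config.species_tree.strip() + "\n")

    gene_truth_rows = []
    for g in range(config.n_genes):
        unit = f"gene_{g:04d}"
        rng = unit_rng(config.seed, unit)
        beta = float(rng.uniform(0.0, 1.0))
        tips, truth = simulate_gene(beta, tree, config, rng, unit_id=unit)
        write_fasta(sorted(tips.items()), outdir / "genes" / f"{unit}.fa")
        gene_truth_rows.append(truth)

    te_truth_rows = []
    for spec in config.te_specs:
        rng = unit_rng(config.seed, spec.unit_id)
        tips, truth = simulate_te(spec, tree, config, rng)
        write_fasta(sorted(tips.items()), outdir / "tes" / f"{spec.unit_id}.fa")
        te_truth_rows.append(truth)

    def dump_truth(rows: list[SimTruth], path: Path) -> None:
        cols = ["unit_id", "kind", "beta", "r_s", "mode", "donor",
                "recipient", "t_ht_my"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for t in rows:
                d = asdict(t)
                fh.write("\t".join(str(d[c]) for c in cols) + "\n")

    dump_truth(gene_truth_rows, outdir / "truth_genes.tsv")
    dump_truth(te_truth_rows, outdir / "truth_tes.tsv")

    with open(outdir / "divergence.tsv", "w") as fh:
        fh.write("species_a\tspecies_b\tdivergence_my\n")
        for a, b, t in _pairwise_divergence_table(tree):
            fh.write(f"{a}\t{b}\t{t}\n")

    # a small intragenomic burst for the K2P dating path
    rng = unit_rng(config.seed, "copy_burst")
    consensus = _to_string(_draw_root(config.codons_per_te, 0.0, rng))
    burst = simulate_copy_burst(consensus, age_my=5.0, per_site_rate=0.004,
                                n_copies=20, rng=rng)
    write_fasta([("consensus", consensus)], outdir / "copies" / "consensus.fa")
    write_fasta([(f"copy_{i:03d}", s) for i, s in enumerate(burst)],
                outdir / "copies" / "burst.fa")

    # toy genome with planted copies and the matching homology-hit table
    rng = unit_rng(config.seed, "toy_genome")
    background = "".join(rng.choice(list(_BASES), size=3000))
    insert = consensus[:900]
    # plantings at [500, 1400) and [2900, 3800), separated by > max_gap
    contig = background[:500] + insert + background[500:2000] + insert + \
        background[2000:]
    write_fasta([("contig_1", contig)], outdir / "genome.fa")
    with open(outdir / "hits.tsv", "w") as fh:
        # first planting fragmented into two HSPs; 1-based inclusive coords
        rows = [
            ("te_toy", "contig_1", 98.0, 500, 1, 500, 501, 1000, 1e-100, 800.0),
            ("te_toy", "contig_1", 97.0, 400, 501, 900, 1001, 1400, 1e-90, 650.0),
            ("te_toy", "contig_1", 99.0, 900, 1, 900, 2901, 3800, 1e-150, 1500.0),
            ("te_toy", "contig_1", 88.0, 100, 1, 100, 4500, 4599, 1e-5, 150.0),
        ]
        for q, s, ident, alen, qs, qe, ss, se, ev, bit in rows:
            fh.write(
                f"{q}\t{s}\t{ident}\t{alen}\t0\t0\t{qs}\t{qe}\t{ss}\t{se}\t"
                f"{ev}\t{bit}\n"
            )

    cfg = asdict(config)
    cfg["te_specs"] = [asdict(s) for s in config.te_specs]
    (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    return outdir
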