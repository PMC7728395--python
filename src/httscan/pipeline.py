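"""End-to-end wiring: alignments -> (CUB, dS) points -> calls -> dates.

This module turns per-unit multi-species alignments (one FASTA per gene or
TE family, records named by species) into the pairwise observations the
transfer test consumes, fits the per-species-pair gene regressions, tests
every TE family, aggregates family-level events and dates the significant
pairs with rates estimated from the same genes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_stats, dating, htt_test
from .io_formats import read_fasta

__all__ = [
    "pair_points_for_unit",
    "fit_models_from_genes",
    "run_pipeline",
]


def pair_points_for_unit(
    unit_id: str, tips: dict[str, str], kind: str = "gene"
) -> list[htt_test.PairPoint]:
    """One (CUB, dS) observation per unordered species pair carrying the unit.

    ``cub`` is the mean Nc of the two sequences; pairs whose dS is
    saturated get dS = NaN and are excluded downstream.
    """
    species = sorted(tips)
    enc_cache = {sp: codon_stats.enc(tips[sp]).Nc for sp in species}
    points = []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            div = codon_stats.ds_ng86(tips[a], tips[b])
            points.append(
                htt_test.PairPoint(
                    unit_id=unit_id,
                    species_a=a,
                    species_b=b,
                    dS=div.dS,
                    cub=(enc_cache[a] + enc_cache[b]) / 2.0,
                    kind=kind,
                    n_codons=div.n_codons,
                )
            )
    return points


def fit_models_from_genes(
    gene_alignments: dict[str, dict[str, str]], min_genes: int = 10
) -> dict[frozenset, htt_test.RegressionModel]:
    """Fit the dS ~ CUB gene regression for every species pair seen."""
    by_pair: dict[frozenset, list[htt_test.PairPoint]] = {}
    for unit_id, tips in gene_alignments.items():
        for p in pair_points_for_unit(unit_id, tips, kind="gene"):
            by_pair.setdefault(p.pair, []).append(p)
    return {
        pair: htt_test.fit_gene_regression(points, min_genes=min_genes)
        for pair, points in by_pair.items()
    }


def _read_alignment_dir(path: Path) -> dict[str, dict[str, str]]:
    out = {}
    for fasta in sorted(path.glob("*.fa")) + sorted(path.glob("*.fasta")):
        out[fasta.stem] = dict(read_fasta(fasta))
    return out


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    simdir: str | Path,
    outdir: str | Path,
    alpha: float = 0.01,
    min_genes: int = 10,
    seed: int = 0,
) -> dict:
    """Run the full inference on a study bundle and write result tables.

    Expects the ``generate_study`` layout (``genes/``, ``tes/``,
    ``divergence.tsv``).  Writes gene-regression diagnostics, the pairwise
    call table, family events, per-species counts, network edges, dated
    events and a manifest echoing every threshold plus input checksums.
    Returns the result bundle as a dict of DataFrames.
    """
    simdir = Path(simdir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = _read_alignment_dir(simdir / "genes")
    tes = _read_alignment_dir(simdir / "tes")
    if not genes:
        raise FileNotFoundError(f"no gene alignments under {simdir / 'genes'}")

    models = fit_models_from_genes(genes, min_genes=min_genes)

    div_path = simdir / "divergence.tsv"
    divergence = {}
    if div_path.exists():
        df = pd.read_csv(div_path, sep="\t")
        for _, row in df.iterrows():
            divergence[frozenset({row["species_a"], row["species_b"]})] = float(
                row["divergence_my"]
            )

    # per-pair synonymous rate from the same orthologous genes
    rate_by_pair: dict[frozenset, float] = {}
    gene_ds_by_pair: dict[frozenset, list[float]] = {}
    for unit_id, tips in genes.items():
        for p in pair_points_for_unit(unit_id, tips):
            gene_ds_by_pair.setdefault(p.pair, []).append(p.dS)
    for pair, ds_values in gene_ds_by_pair.items():
        if pair in divergence:
            rate_by_pair[pair] = dating.estimate_rate(ds_values,
                                                      divergence[pair])

    call_rows, dated = [], []
    family_calls: dict[str, list[htt_test.HttCall]] = {}
    for family_id, tips in tes.items():
        points = pair_points_for_unit(family_id, tips, kind="te")
        _, calls = htt_test.htt_matrix(points, models, alpha=alpha)
        family_calls[family_id] = calls
        for c in calls:
            call_rows.append(
                {
                    "family_id": c.family_id,
                    "species_a": c.species_a,
                    "species_b": c.species_b,
                    "te_dS": c.te_dS,
                    "expected_dS": c.expected_dS,
                    "t": c.t_statistic,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
            )
            pair = frozenset({c.species_a, c.species_b})
            if c.significant and pair in rate_by_pair:
                res = dating.date_htt(
                    max(c.te_dS, 0.0), "pair", {"pair": rate_by_pair[pair]},
                    family_id=c.family_id, species_a=c.species_a,
                    species_b=c.species_b,
                )
                dated.append(
                    {
                        "family_id": res.family_id,
                        "species_a": res.species_a,
                        "species_b": res.species_b,
                        "k": res.k,
                        "r": res.r,
                        "T_my": res.T,
                    }
                )

    events, per_species, edges = htt_test.call_family_events(family_calls)
    diagnostics = pd.DataFrame(
        [htt_test.check_assumptions(m) for m in models.values()]
    )

    calls_df = pd.DataFrame(call_rows)
    dating_df = pd.DataFrame(dated)
    calls_df.to_csv(outdir / "htt_calls.tsv", sep="\t", index=False)
    events.to_csv(outdir / "family_events.tsv", sep="\t", index=False)
    per_species.to_csv(outdir / "per_species_counts.tsv", sep="\t")
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    dating_df.to_csv(outdir / "dating.tsv", sep="\t", index=False)
    diagnostics.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)

    manifest = {
        "alpha": alpha,
        "min_genes": min_genes,
        "seed": seed,
        "n_genes": len(genes),
        "n_te_families": len(tes),
        "n_species_pairs": len(models),
        "inputs": {
            str(p.relative_to(simdir)): _file_checksum(p)
            for p in sorted(simdir.rglob("*"))
            if p.is_file()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "calls": calls_df,
        "events": events,
        "per_species": per_species,
        "edges": edges,
        "dating": dating_df,
        "diagnostics": diagnostics,
        "models": models,
    }
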