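"""The dS–codon-usage-bias consistency test for horizontal transfer.

Vertically inherited sequences in two species have diverged for the same
length of time, so their synonymous divergence (dS) is predicted by host
effects alone — chiefly codon usage bias, which modulates the synonymous
substitution rate.  Per species pair, dS of single-copy orthologous host
genes is regressed on their codon usage (Wright's Nc); a transposable
element whose dS falls significantly *below* this vertical expectation has
not been diverging since the species split and is called horizontally
transferred.  Significance uses the studentized prediction residual

    t = (dS_TE - dS_hat) / (s * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx))

against Student's t with n - 2 degrees of freedom, one-tailed (lower),
with alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PairPoint",
    "RegressionModel",
    "HttCall",
    "fit_gene_regression",
    "te_ht_pvalue",
    "htt_matrix",
    "call_family_events",
    "check_assumptions",
]

ALPHA_DEFAULT = 0.01


@dataclass(frozen=True)
class PairPoint:
    """One (codon-usage, dS) observation for a species pair.

    ``cub`` is the mean Nc of the two aligned sequences; ``kind`` is
    "gene" for the orthologs anchoring the regression and "te" for the
    element under test.
    """

    unit_id: str
    species_a: str
    species_b: str
    dS: float
    cub: float
    kind: str = "gene"
    n_codons: int | None = None

    def __post_init__(self) -> None:
        if not 20.0 <= self.cub <= 61.0:
            raise ValueError("cub outside the Nc range [20, 61]")
        if self.kind not in {"gene", "te"}:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def pair(self) -> frozenset:
        return frozenset({self.species_a, self.species_b})


@dataclass
class RegressionModel:
    """An OLS fit of gene dS on codon usage for one species pair."""

    species_a: str
    species_b: str
    slope: float
    intercept: float
    residual_sd: float
    df: int
    n: int
    x_mean: float
    sxx: float
    mean_n_codons: float | None
    residuals: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def predict(self, cub: float) -> float:
        return self.intercept + self.slope * cub

    @property
    def pair(self) -> frozenset:
        return frozenset({self.species_a, self.species_b})


@dataclass(frozen=True)
class HttCall:
    """One pairwise horizontal-transfer decision for a TE family."""

    family_id: str
    species_a: str
    species_b: str
    te_dS: float
    expected_dS: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = ALPHA_DEFAULT


def fit_gene_regression(
    gene_points: list[PairPoint], min_genes: int = 10
) -> RegressionModel:
    """Ordinary least squares of gene dS on codon usage for one species pair.

    Saturated (NaN) dS points are excluded before fitting.  Raises if fewer
    than ``min_genes`` usable points remain (and always if df < 1), or if
    codon usage has zero variance (slope undefined).
    """
    usable = [p for p in gene_points if np.isfinite(p.dS)]
    if len(usable) < max(min_genes, 3):
        raise ValueError(
            f"need at least {max(min_genes, 3)} unsaturated gene points, "
            f"have {len(usable)}"
        )
    pairs = {p.pair for p in usable}
    if len(pairs) != 1:
        raise ValueError("gene points span more than one species pair")
    x = np.array([p.cub for p in usable])
    y = np.array([p.dS for p in usable])
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("zero codon-usage variance: slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    resid = np.asarray(fit.resid)
    df = len(usable) - 2
    residual_sd = float(np.sqrt(resid @ resid / df))
    lengths = [p.n_codons for p in usable if p.n_codons]
    return RegressionModel(
        species_a=usable[0].species_a,
        species_b=usable[0].species_b,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
        df=df,
        n=len(usable),
        x_mean=float(x.mean()),
        sxx=sxx,
        mean_n_codons=float(np.mean(lengths)) if lengths else None,
        residuals=resid,
        x=x,
        y=y,
    )


def te_ht_pvalue(
    model: RegressionModel, te_point: PairPoint, alpha: float = ALPHA_DEFAULT
) -> HttCall:
    """One-tailed test of a TE's dS against the vertical expectation.

    Small p means the TE diverged less than vertically inherited genes
    predict at its codon usage — the horizontal-transfer signal.  A
    saturated TE dS cannot be tested and raises.

    Because per-pair dS noise scales inversely with alignment length, the
    new-observation variance term is weighted by (mean gene codons) /
    (TE codons) when both lengths are known; for equal lengths this is the
    textbook studentized prediction residual.
    """
    if not np.isfinite(te_point.dS):
        raise ValueError(
            f"{te_point.unit_id}: saturated dS, call suppressed"
        )
    expected = model.predict(te_point.cub)
    leverage = (te_point.cub - model.x_mean) ** 2 / model.sxx
    length_weight = 1.0
    if model.mean_n_codons and te_point.n_codons:
        length_weight = model.mean_n_codons / te_point.n_codons
    se = model.residual_sd * np.sqrt(length_weight + 1.0 / model.n + leverage)
    if se == 0.0:
        # exact-fit degenerate model: any deviation is infinitely surprising
        t_stat = -np.inf if te_point.dS < expected else (
            0.0 if te_point.dS == expected else np.inf
        )
    else:
        t_stat = (te_point.dS - expected) / se
    p = float(stats.t.cdf(t_stat, model.df)) if np.isfinite(t_stat) else (
        0.0 if t_stat < 0 else 1.0
    )
    if t_stat == 0.0:
        p = 0.5
    return HttCall(
        family_id=te_point.unit_id,
        species_a=te_point.species_a,
        species_b=te_point.species_b,
        te_dS=te_point.dS,
        expected_dS=float(expected),
        t_statistic=float(t_stat),
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )


def htt_matrix(
    te_points: list[PairPoint],
    models: dict[frozenset, RegressionModel],
    alpha: float = ALPHA_DEFAULT,
) -> tuple[pd.DataFrame, list[HttCall]]:
    """Pairwise p-value matrix for one family across the species sharing it.

    Cells without a usable TE point or gene model are NA.  Returns the
    symmetric matrix (species x species) and the list of calls made.
    """
    species = sorted({s for p in te_points for s in (p.species_a, p.species_b)})
    mat = pd.DataFrame(np.nan, index=species, columns=species)
    calls: list[HttCall] = []
    for point in te_points:
        model = models.get(point.pair)
        if model is None or not np.isfinite(point.dS):
            continue
        call = te_ht_pvalue(model, point, alpha=alpha)
        calls.append(call)
        mat.loc[point.species_a, point.species_b] = call.p_value
        mat.loc[point.species_b, point.species_a] = call.p_value
    return mat, calls


def call_family_events(
    family_calls: dict[str, list[HttCall]],
    family_classes: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Aggregate pairwise calls into family events, species counts and edges.

    A family is a horizontal-transfer family iff it has at least one
    significant pair; however many significant pairs it shows, it counts as
    a single event (the minimal-scenario reconstruction is out of reach, so
    families are the unit of counting).  Per species, the count is the
    number of such families whose significant pairs involve that species,
    broken down by TE class when ``family_classes`` is given; the edge
    table counts families per species pair for network rendering.
    """
    family_classes = family_classes or {}
    event_rows: list[dict] = []
    edge_count: dict[tuple[str, str], set[str]] = {}
    species_families: dict[tuple[str, str], set[str]] = {}
    for family_id, calls in family_calls.items():
        sig = [c for c in calls if c.significant]
        te_class = family_classes.get(family_id, "unknown")
        event_rows.append(
            {
                "family_id": family_id,
                "te_class": te_class,
                "n_pairs_tested": len(calls),
                "n_pairs_significant": len(sig),
                "is_htt_family": bool(sig),
                "min_p_value": min((c.p_value for c in calls), default=np.nan),
            }
        )
        involved = set()
        for c in sig:
            involved.update((c.species_a, c.species_b))
            edge = tuple(sorted((c.species_a, c.species_b)))
            edge_count.setdefault(edge, set()).add(family_id)
        for sp in involved:
            species_families.setdefault((sp, te_class), set()).add(family_id)
    events = pd.DataFrame(event_rows)
    per_species = pd.DataFrame(
        [
            {"species": sp, "te_class": cls, "n_htt_families": len(fams)}
            for (sp, cls), fams in sorted(species_families.items())
        ]
    )
    if not per_species.empty:
        per_species = (
            per_species.pivot_table(
                index="species", columns="te_class", values="n_htt_families",
                fill_value=0, aggfunc="sum",
            )
            .astype(int)
        )
        per_species["total"] = per_species.sum(axis=1)
        per_species = per_species.sort_values("total", ascending=False)
    edges = pd.DataFrame(
        [
            {"species_a": a, "species_b": b, "n_families": len(fams)}
            for (a, b), fams in sorted(edge_count.items())
        ]
    )
    return events, per_species, edges


def check_assumptions(model: RegressionModel, alpha_diag: float = 0.05) -> dict:
    """Diagnostics behind the test's validity for one species pair.

    Kolmogorov–Smirnov test of standardized residuals against the standard
    normal (the t-based p-values assume Gaussian residuals), plus the
    Pearson correlation of dS with codon usage (the relation should be
    linear and present).  Pairs failing either check at ``alpha_diag`` are
    flagged.  A zero-variance residual vector is reported as an exact fit
    rather than tested.
    """
    resid = model.residuals
    out: dict = {
        "species_a": model.species_a,
        "species_b": model.species_b,
        "n": model.n,
    }
    sd = resid.std(ddof=2)
    if np.allclose(resid, 0.0, atol=1e-10):
        out.update(
            exact_fit=True, ks_statistic=np.nan, ks_p=np.nan,
            pearson_r=np.nan, pearson_p=np.nan, flagged=False,
        )
        return out
    z = resid / sd
    ks_stat, ks_p = stats.kstest(z, "norm")
    r, r_p = stats.pearsonr(model.x, model.y)
    out.update(
        exact_fit=False,
        ks_statistic=float(ks_stat),
        ks_p=float(ks_p),
        pearson_r=float(r),
        pearson_p=float(r_p),
        flagged=bool(ks_p < alpha_diag or r_p > alpha_diag),
    )
    return out
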