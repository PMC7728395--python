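"""Simulation studies that measure the statistical behaviour of the test.

Three canned experiments, each fully seeded:

* ``run_calibration`` — vertically inherited TEs only; the significant
  fraction at alpha = 0.01 should match alpha and the p-values should be
  uniform, since under the null the TE point is exchangeable with the
  gene points anchoring the regression.
* ``run_power`` — a transfer at 10% of the species divergence time; the
  TE's dS is ~10x below the vertical expectation, and the experiment
  measures how often the one-tailed test catches it.
* ``run_dating_recovery`` — transfers of known age dated with the true
  simulated rate, measuring the relative error of T = k / (2r) driven by
  Poisson substitution noise alone.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import simulate
from .codon_stats import ds_ng86, enc
from .htt_test import PairPoint, fit_gene_regression, te_ht_pvalue
from .pipeline import fit_models_from_genes, pair_points_for_unit

__all__ = [
    "CALIBRATION_TREE",
    "TWO_SPECIES_TREE",
    "run_calibration",
    "run_power",
    "run_dating_recovery",
    "beta_for_rate",
]

#: five ultrametric species, 10 My deep: ten species pairs per study
CALIBRATION_TREE = "(((sp1:4,sp2:4):3,sp3:7):3,(sp4:5,sp5:5):5);"
#: a single donor/recipient pair split 10 My ago
TWO_SPECIES_TREE = "(donor:10,recipient:10);"


def beta_for_rate(target_rate: float, r_max: float, lambda_cub: float) -> float:
    """Invert r_s(beta) by bisection: the bias giving a target synonymous rate."""
    lo, hi = 0.0, 1.0
    synonymous = simulate.synonymous_rate
    if not (synonymous(hi, r_max, lambda_cub) <= target_rate
            <= synonymous(lo, r_max, lambda_cub)):
        raise ValueError("target rate outside the attainable range")
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if synonymous(mid, r_max, lambda_cub) > target_rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _one_pair_study(
    seed: int, label: str, n_genes: int, config: simulate.SimConfig,
) -> "object":
    """Fresh 50-gene dS ~ CUB regression for the donor/recipient pair."""
    gene_points = []
    for g in range(n_genes):
        unit = f"{label}_gene_{g:03d}"
        rng = simulate.unit_rng(seed, unit)
        beta = float(rng.uniform(0.0, 1.0))
        tips, _ = simulate.simulate_gene(beta, TWO_SPECIES_TREE, config, rng,
                                         unit_id=unit)
        gene_points.extend(pair_points_for_unit(unit, tips))
    return fit_gene_regression(gene_points)


def _te_point(unit: str, tips: dict[str, str]) -> PairPoint | None:
    a, b = sorted(tips)
    div = ds_ng86(tips[a], tips[b])
    if not np.isfinite(div.dS):
        return None
    return PairPoint(
        unit_id=unit, species_a=a, species_b=b, dS=div.dS,
        cub=(enc(tips[a]).Nc + enc(tips[b]).Nc) / 2.0, kind="te",
        n_codons=div.n_codons,
    )


def run_calibration(
    seed: int,
    n_tests: int = 1000,
    n_genes: int = 50,
    alpha: float = 0.01,
) -> dict:
    """Null calibration: vertical TEs against fresh per-test regressions.

    Each of the ``n_tests`` tests simulates its own 50-gene regression for
    a species pair split 10 My ago and one fresh vertical 600-codon TE,
    so the resulting p-values are independent — the assumption behind
    both the exact binomial acceptance interval for the significant
    fraction and the Kolmogorov–Smirnov uniformity check.  Returns the
    p-values, the significant fraction with its binomial 95% interval,
    and the KS statistic and p-value.
    """
    config = simulate.SimConfig(species_tree=TWO_SPECIES_TREE, seed=seed,
                                n_genes=n_genes)
    pvalues = []
    for t in range(n_tests):
        model = _one_pair_study(seed, f"cal_{t:04d}", n_genes, config)
        unit = f"cal_{t:04d}_te"
        rng = simulate.unit_rng(seed, unit)
        beta = float(rng.uniform(0.0, 1.0))
        spec = simulate.TeSpec(unit_id=unit, mode="vertical", beta=beta)
        tips, _ = simulate.simulate_te(spec, TWO_SPECIES_TREE, config, rng)
        point = _te_point(unit, tips)
        if point is None:
            continue
        call = te_ht_pvalue(model, point, alpha=alpha)
        pvalues.append(call.p_value)
    pvalues = np.array(pvalues)
    n = pvalues.size
    n_sig = int((pvalues < alpha).sum())
    lo = int(stats.binom.ppf(0.025, n, alpha))
    hi = int(stats.binom.ppf(0.975, n, alpha))
    ks_stat, ks_p = stats.kstest(pvalues, "uniform")
    return {
        "n_tests": n,
        "n_significant": n_sig,
        "significant_fraction": n_sig / n,
        "binomial_interval_fraction": (lo / n, hi / n),
        "in_binomial_interval": lo <= n_sig <= hi,
        "ks_statistic": float(ks_stat),
        "ks_p": float(ks_p),
        "pvalues": pvalues,
    }


def run_power(
    seed: int,
    n_reps: int = 200,
    t_ht_my: float = 1.0,
    te_rate: float = 0.0176,
    n_genes: int = 50,
    alpha: float = 0.01,
) -> dict:
    """Detection frequency for transfers at 10% of the species divergence.

    Each replicate simulates a fresh 50-gene regression for a species pair
    split 10 My ago and one 600-codon TE transferred ``t_ht_my`` ago at a
    synonymous rate of ``te_rate`` (the within-Anophelinae host estimate).
    """
    config = simulate.SimConfig(species_tree=TWO_SPECIES_TREE, seed=seed,
                                n_genes=n_genes)
    beta_te = beta_for_rate(te_rate, config.r_max, config.lambda_cub)
    detected = 0
    pvalues = []
    for rep in range(n_reps):
        model = _one_pair_study(seed, f"pow_{rep:04d}", n_genes, config)
        unit = f"pow_{rep:04d}_te"
        rng = simulate.unit_rng(seed, unit)
        spec = simulate.TeSpec(unit_id=unit, mode="horizontal",
                               donor="donor", recipient="recipient",
                               t_ht_my=t_ht_my, beta=beta_te)
        tips, _ = simulate.simulate_te(spec, TWO_SPECIES_TREE, config, rng)
        te_point = _te_point(unit, tips)
        if te_point is None:
            continue
        call = te_ht_pvalue(model, te_point, alpha=alpha)
        pvalues.append(call.p_value)
        if call.significant:
            detected += 1
    return {
        "n_reps": n_reps,
        "n_detected": detected,
        "detection_frequency": detected / n_reps,
        "median_p": float(np.median(pvalues)),
    }


def run_dating_recovery(
    seed: int,
    n_reps: int = 200,
    t_ht_my: float = 2.0,
) -> dict:
    """Relative error of T = k / (2r) when the true rate is known.

    k is the NG86 dS between the donor and recipient TE copies; dividing
    by twice the simulator's true synonymous rate recovers the transfer
    age up to Poisson substitution noise at 600 codons.
    """
    config = simulate.SimConfig(species_tree=TWO_SPECIES_TREE, seed=seed)
    rel_errors = []
    estimates = []
    for rep in range(n_reps):
        unit = f"date_{rep:04d}_te"
        rng = simulate.unit_rng(seed, unit)
        beta = float(rng.uniform(0.0, 0.8))
        spec = simulate.TeSpec(unit_id=unit, mode="horizontal",
                               donor="donor", recipient="recipient",
                               t_ht_my=t_ht_my, beta=beta)
        tips, truth = simulate.simulate_te(spec, TWO_SPECIES_TREE, config, rng)
        k = ds_ng86(tips["donor"], tips["recipient"]).dS
        if not np.isfinite(k):
            continue
        t_hat = k / (2.0 * truth.r_s)
        estimates.append(t_hat)
        rel_errors.append(abs(t_hat - t_ht_my) / t_ht_my)
    rel_errors = np.array(rel_errors)
    return {
        "n_reps": len(rel_errors),
        "t_ht_my": t_ht_my,
        "median_relative_error": float(np.median(rel_errors)),
        "mean_estimate": float(np.mean(estimates)),
        "estimates": np.array(estimates),
    }
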