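"""Downstream accounting around the horizontal-transfer calls.

Covers four independent follow-ups: discriminating true transfer from
introgression by comparing TE flanking sequence between the two species
(introgressed segments carry their flanks along, transfers do not); the
fraction of each genome covered by horizontally transferred families;
rank correlations of that coverage with genome size; the point-biserial
correlation of transfer counts with geographic range overlap; and the
long-range screen for the same families in non-mosquito assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._align import identity_coverage
from .copy_recovery import merge_hsps
from .io_formats import GenomeInterval, Hsp

__all__ = [
    "FlankComparison",
    "CoverageReport",
    "classify_introgression",
    "genome_htt_fraction",
    "correlate_fraction_size",
    "geo_correlation",
    "long_range_screen",
]


@dataclass(frozen=True)
class FlankComparison:
    family_id: str
    species_a: str
    species_b: str
    upstream_identity: float | None
    downstream_identity: float | None
    flank_length: int
    verdict: str  # HTT | putative_introgression | indeterminate


@dataclass(frozen=True)
class CoverageReport:
    species: str
    htt_bp: int
    genome_size: int
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction outside [0, 1]")


def _flank_shared(
    flank_a: str | None, flank_b: str | None,
    min_flank: int, shared_identity: float, shared_coverage: float,
) -> tuple[float | None, bool | None]:
    """(identity, shared?) for one side; (None, None) if unevaluable."""
    if not flank_a or not flank_b:
        return None, None
    if len(flank_a) < min_flank or len(flank_b) < min_flank:
        return None, None
    ident, cov = identity_coverage(flank_a, flank_b)
    return ident, bool(ident >= shared_identity and cov >= shared_coverage)


def classify_introgression(
    family_id: str,
    species_a: str,
    species_b: str,
    upstream_a: str | None,
    upstream_b: str | None,
    downstream_a: str | None,
    downstream_b: str | None,
    min_flank: int = 3000,
    max_flank: int = 5000,
    shared_identity: float = 0.70,
    shared_coverage: float = 0.50,
) -> FlankComparison:
    """Decide HTT vs putative introgression from the copies' flanking sequence.

    Flanks longer than ``max_flank`` are clipped to it; flanks shorter than
    ``min_flank`` (e.g. copies near contig edges) make that side
    unevaluable.  A side is "shared" when global-alignment identity reaches
    ``shared_identity`` over at least ``shared_coverage`` of the shorter
    flank.  Any shared side means the surrounding segment travelled with
    the element: putative introgression.  All evaluable sides different
    means only the element moved: HTT.  No evaluable side: indeterminate.
    """
    def clip(f: str | None) -> str | None:
        return f[:max_flank] if f else f

    up_ident, up_shared = _flank_shared(
        clip(upstream_a), clip(upstream_b), min_flank, shared_identity,
        shared_coverage,
    )
    down_ident, down_shared = _flank_shared(
        clip(downstream_a), clip(downstream_b), min_flank, shared_identity,
        shared_coverage,
    )
    evaluable = [s for s in (up_shared, down_shared) if s is not None]
    if not evaluable:
        verdict = "indeterminate"
    elif any(evaluable):
        verdict = "putative_introgression"
    else:
        verdict = "HTT"
    flank_len = min(
        [len(f) for f in (upstream_a, upstream_b, downstream_a, downstream_b)
         if f] or [0]
    )
    return FlankComparison(
        family_id=family_id,
        species_a=species_a,
        species_b=species_b,
        upstream_identity=up_ident,
        downstream_identity=down_ident,
        flank_length=min(flank_len, max_flank),
        verdict=verdict,
    )


def _merge_intervals(intervals: list[GenomeInterval]) -> list[tuple[str, int, int]]:
    """Union of intervals per contig, strand-blind."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: list[tuple[str, int, int]] = []
    for contig, spans in by_contig.items():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((contig, cur_s, cur_e))
    return merged


def genome_htt_fraction(
    htt_intervals: dict[str, list[GenomeInterval]],
    genome_sizes: dict[str, int],
) -> list[CoverageReport]:
    """Per-species genome fraction covered by HTT-family copies.

    Intervals from all families are unioned (overlaps and duplicates
    counted once) before summing.  Intervals beyond the recorded genome
    size raise.
    """
    reports = []
    for species, size in sorted(genome_sizes.items()):
        intervals = htt_intervals.get(species, [])
        for iv in intervals:
            if iv.end > size:
                raise ValueError(
                    f"{species}: interval [{iv.start}, {iv.end}) on "
                    f"{iv.contig} exceeds genome size {size}"
                )
        bp = sum(e - s for _, s, e in _merge_intervals(intervals))
        reports.append(
            CoverageReport(species=species, htt_bp=bp, genome_size=size,
                           fraction=bp / size)
        )
    return reports


def correlate_fraction_size(
    values_x: list[float], values_y: list[float]
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with its p-value."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def geo_correlation(
    overlap: list[int], htt_counts: list[float]
) -> tuple[float, float]:
    """Point-biserial correlation of transfer counts with range overlap.

    ``overlap`` is binary per species pair, ``htt_counts`` the number of
    transfers for the same pairs.  Identical to Pearson correlation with
    the binary variable coded 0/1; two-sided p via the t transform.
    """
    x = np.asarray(overlap, dtype=float)
    y = np.asarray(htt_counts, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("overlap values must be binary")
    if len(np.unique(x)) < 2:
        raise ValueError("both overlap groups must be represented")
    if len(np.unique(y)) < 2:
        raise ValueError("constant transfer counts: correlation undefined")
    r, p = stats.pointbiserialr(x, y)
    return float(r), float(p)


def long_range_screen(
    hsps: list[Hsp],
    query_lengths: dict[str, int],
    contig_assembly: dict[str, str],
    assembly_species: dict[str, str],
    min_query_coverage: float = 0.80,
    min_identity: float = 0.80,
    min_copies: int = 5,
) -> pd.DataFrame:
    """Screen merged hits of family consensuses against external genomes.

    Hits are merged into copies per assembly with the standard copy
    recovery rule; a copy "qualifies" when its (union) query coverage
    exceeds ``min_query_coverage`` and its length-weighted identity is at
    least ``min_identity``.  A (family, species) is a candidate long-range
    transfer when some assembly holds a qualifying copy alongside a copy
    count strictly greater than ``min_copies``, or — for species with more
    than one assembly — when qualifying copies appear in a strict majority
    of its assemblies regardless of copy number.
    """
    records: dict[tuple[str, str], dict] = {}
    hsps_by_assembly: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        if h.subject_id not in contig_assembly:
            raise KeyError(f"contig {h.subject_id!r} has no assembly mapping")
        assembly = contig_assembly[h.subject_id]
        hsps_by_assembly.setdefault((h.query_id, assembly), []).append(h)

    assemblies_of_species: dict[str, set[str]] = {}
    for asm, sp in assembly_species.items():
        assemblies_of_species.setdefault(sp, set()).add(asm)

    per_fam_assembly: dict[tuple[str, str], dict] = {}
    for (family, assembly), hits in hsps_by_assembly.items():
        qlen = query_lengths[family]
        copies = merge_hsps(hits, max_gap=1000)
        n_copies = len(copies)
        qualifying = 0
        best_cov = best_ident = 0.0
        for copy in copies:
            members = [
                h for h in hits
                if h.subject_id == copy.location.contig
                and h.strand == copy.location.strand
                and h.s_start >= copy.location.start
                and h.s_end <= copy.location.end
            ]
            q_spans = _merge_intervals(
                [GenomeInterval("q", h.q_start, h.q_end) for h in members]
            )
            coverage = sum(e - s for _, s, e in q_spans) / qlen
            total = sum(h.s_end - h.s_start for h in members)
            identity = (
                sum(h.percent_identity * (h.s_end - h.s_start) for h in members)
                / total
            )
            best_cov = max(best_cov, coverage)
            best_ident = max(best_ident, identity)
            if coverage > min_query_coverage and identity >= min_identity:
                qualifying += 1
        per_fam_assembly[(family, assembly)] = {
            "n_copies": n_copies,
            "qualifying": qualifying,
            "best_coverage": best_cov,
            "best_identity": best_ident,
        }

    rows = []
    fam_species = sorted(
        {
            (family, assembly_species[assembly])
            for family, assembly in per_fam_assembly
        }
    )
    for family, species in fam_species:
        assemblies = sorted(assemblies_of_species[species])
        infos = [
            per_fam_assembly.get((family, a),
                                 {"n_copies": 0, "qualifying": 0,
                                  "best_coverage": 0.0, "best_identity": 0.0})
            for a in assemblies
        ]
        copy_rule = any(
            i["qualifying"] > 0 and i["n_copies"] > min_copies for i in infos
        )
        with_quals = sum(1 for i in infos if i["qualifying"] > 0)
        majority_rule = len(assemblies) > 1 and with_quals * 2 > len(assemblies)
        rows.append(
            {
                "family_id": family,
                "species": species,
                "n_assemblies": len(assemblies),
                "assemblies_with_qualifying": with_quals,
                "max_copies": max(i["n_copies"] for i in infos),
                "best_coverage": max(i["best_coverage"] for i in infos),
                "best_identity": max(i["best_identity"] for i in infos),
                "copy_rule": copy_rule,
                "majority_rule": majority_rule,
                "candidate": copy_rule or majority_rule,
            }
        )
    return pd.DataFrame(rows)
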