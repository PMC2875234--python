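"""Group-level statistics: imprinted vs genome, paralog selection/enrichment,
SNP-density comparisons.

Group comparisons use the two-sided Mann-Whitney rank-sum test (exact for
small samples, normal approximation with tie correction otherwise);
contingency tables use the Pearson chi-square without continuity correction.
No multiple-testing correction is applied: each reported p-value answers its
own question, as in the comparative tables these routines emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median

import numpy as np
from scipy import stats

from .io import GenePairRecord, GeneGroupAssignment, ParalogRecord, ValidationError


def select_best_homolog(candidates: list[GenePairRecord]) -> GenePairRecord:
    """When several homologs exist for one gene/species pair, keep the one
    with the highest protein identity; ties break to the lexicographically
    lowest gene_id."""
    if not candidates:
        raise ValueError("no candidate homologs")
    return max(candidates, key=lambda r: (r.protein_identity, _neg_lex(r.gene_id)))


def _neg_lex(s: str) -> tuple:
    # max() picks the highest key; invert character order so the smallest
    # gene_id wins on identity ties
    return tuple(-ord(c) for c in s)


def select_representative_paralog(records: list[ParalogRecord]) -> ParalogRecord | None:
    """The rank-1 (evolutionarily most recent) paralog, or None if the gene
    has no paralogs."""
    if not records:
        return None
    rank1 = [r for r in records if r.rank == 1]
    if len(rank1) != 1:
        raise ValidationError(
            f"{records[0].gene_id}: expected exactly one rank-1 paralog, found {len(rank1)}"
        )
    return rank1[0]


@dataclass
class GroupSummary:
    """Mean +/- sd and median of one statistic within one gene group."""

    group: str
    statistic: str
    n: int
    mean: float | None
    sd: float | None
    median: float | None


def _summary(group: str, statistic: str, values: list[float]) -> GroupSummary:
    values = [v for v in values if v is not None and not math.isnan(v)]
    if not values:
        return GroupSummary(group, statistic, 0, None, None, None)
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GroupSummary(group, statistic, len(arr), float(arr.mean()), sd, float(median(arr)))


def summarize(
    values_by_gene: dict[str, dict[str, float | None]],
    assignments: list[GeneGroupAssignment],
    groups: tuple[str, ...] = ("imprinted", "maternal", "paternal", "background"),
) -> list[GroupSummary]:
    """Per-group mean, sd (n-1 denominator) and median of each statistic.

    ``values_by_gene`` maps gene_id -> {statistic -> value or None}; None
    values (e.g. Ks-discarded entries) drop out of that statistic only, so a
    gene still contributes its identities when its Ks is unusable.
    ``imprinted`` is the union of the maternal and paternal groups.
    """
    group_of = {a.gene_id: a.group for a in assignments}
    statistics: list[str] = sorted({k for d in values_by_gene.values() for k in d})
    out: list[GroupSummary] = []
    for group in groups:
        if group == "imprinted":
            members = [g for g, grp in group_of.items() if grp in ("maternal", "paternal")]
        else:
            members = [g for g, grp in group_of.items() if grp == group]
        for stat in statistics:
            vals = [
                values_by_gene[g].get(stat)
                for g in members
                if g in values_by_gene
            ]
            out.append(_summary(group, stat, vals))
    return out


@dataclass
class GroupComparison:
    p_value: float
    statistic: float
    direction: str  # "a_higher", "b_higher", "none"
    n_a: int
    n_b: int


def compare_groups(
    values_a: list[float], values_b: list[float], alternative: str = "two-sided"
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of two value sets.

    Exact null distribution when the smaller sample has <= 8 observations
    and there are no ties; normal approximation with tie correction
    otherwise.  Direction is reported from the medians.
    """
    a = [v for v in values_a if v is not None and not math.isnan(v)]
    b = [v for v in values_b if v is not None and not math.isnan(v)]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    ties = len(set(a) | set(b)) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    med_a, med_b = median(a), median(b)
    direction = "a_higher" if med_a > med_b else "b_higher" if med_b > med_a else "none"
    return GroupComparison(float(res.pvalue), float(res.statistic), direction, len(a), len(b))


@dataclass
class EnrichmentResult:
    """Pearson chi-square on a 2x2 count table, with row percentages."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    chi_square: float
    p_value: float
    row_percent: tuple[float, float]  # % in the first column, per row, 2 dp


def paralog_enrichment(counts) -> EnrichmentResult:
    """Chi-square (df = 1, no continuity correction) for a 2x2 table of
    [with-feature, without-feature] counts per group; e.g. genes with vs
    without a paralog in the imprinted group vs the autosomal background."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    row_pct = tuple(
        round(100.0 * table[i, 0] / table[i].sum(), 2) if table[i].sum() else float("nan")
        for i in range(2)
    )
    # degenerate margins (all observations in one column) carry no signal
    if (table.sum(axis=0) == 0).any():
        return EnrichmentResult(
            tuple(map(tuple, table.astype(int))), 0.0, 1.0, row_pct
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(tuple(map(tuple, table.astype(int))), float(chi2), float(p), row_pct)


@dataclass
class SnpDepletionReport:
    median_by_group: dict[str, float]
    comparisons: dict[tuple[str, str], GroupComparison]


def snp_depletion_report(
    densities_by_group: dict[str, list[float]],
    baseline: str = "background",
) -> SnpDepletionReport:
    """Median SNP density per kb per group, plus rank-sum comparison of each
    group against the baseline group."""
    medians = {g: float(median(v)) for g, v in densities_by_group.items() if v}
    comparisons = {}
    base = densities_by_group.get(baseline)
    if base:
        for g, vals in densities_by_group.items():
            if g == baseline or not vals:
                continue
            comparisons[(g, baseline)] = compare_groups(vals, base)
    return SnpDepletionReport(medians, comparisons)
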