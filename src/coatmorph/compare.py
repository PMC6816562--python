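"""Same-breed subpopulation comparison of allele distributions.

Builds a populations x allele-classes contingency table of chromosome
counts, picks Fisher's exact test whenever any cell count falls below 5
(Pearson's chi-square otherwise), and applies the Bonferroni scheme: the
primary threshold is 0.05 / n_breeds_tested (30 by default, 29 when a
population drops out), with pairwise follow-up at 0.05 / n_subpopulations.

Fisher's test on tables larger than 2x2 uses exact enumeration of all
tables with the observed margins (Freeman-Halton) while the enumeration
stays tractable, and a seeded Monte-Carlo approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .frequencies import BreedFrequencyTable

__all__ = [
    "ComparisonResult",
    "PairwiseResult",
    "build_contingency",
    "select_test",
    "contingency_test",
    "fisher_exact_rxc",
    "compare_populations",
    "pairwise_followup",
    "DEFAULT_N_BREEDS",
]

DEFAULT_N_BREEDS = 30
EXACT_ENUMERATION_MAX_TOTAL = 200
MC_RESAMPLES = 100_000
_CELL_THRESHOLD = 5


@dataclass
class PairwiseResult:
    population_a: str
    population_b: str
    test: str
    p_value: float
    alpha: float
    significant: bool


@dataclass
class ComparisonResult:
    breed: str
    gene: str
    populations: list[str]
    alleles: list[str]
    table: np.ndarray
    test: str
    p_value: float
    alpha: float
    significant: bool
    status: str = "ok"  # ok | untestable | degenerate
    pairwise: list[PairwiseResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def build_contingency(
    tables: Sequence[BreedFrequencyTable],
    gene_id: str,
    units: str = "chromosomes",
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Populations x classes count matrix; returns (matrix, kept population
    labels, class labels, warnings).  Populations without genotyped dogs at
    the gene are dropped."""
    if units not in ("chromosomes", "genotypes"):
        raise ValueError(f"unknown units {units!r}")
    warnings: list[str] = []
    kept: list[tuple[str, dict]] = []
    for t in tables:
        gf = t.genes.get(gene_id)
        if gf is None or not gf.available:
            warnings.append(f"population {t.population!r}: no genotypes at {gene_id}; dropped")
            continue
        if units == "chromosomes":
            kept.append((t.population, dict(gf.counts)))
        else:
            kept.append(
                (t.population, {"/".join(k): v for k, v in gf.genotype_counts.items()})
            )
    classes = sorted({c for _, counts in kept for c in counts})
    matrix = np.array(
        [[counts.get(c, 0) for c in classes] for _, counts in kept], dtype=np.int64
    )
    return matrix, [p for p, _ in kept], classes, warnings


def select_test(table: np.ndarray) -> str:
    """Fisher whenever any cell count falls below 5, else Pearson chi-square."""
    return "fisher_exact" if (table < _CELL_THRESHOLD).any() else "pearson_chi2"


def _table_logprob(table: np.ndarray, row_margins: np.ndarray, col_margins: np.ndarray) -> float:
    n = row_margins.sum()
    return (
        gammaln(row_margins + 1).sum()
        + gammaln(col_margins + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_margins: np.ndarray, col_margins: np.ndarray, limit: int):
    """Yield all non-negative integer tables with the given margins, or raise
    OverflowError after `limit` tables."""
    n_rows = len(row_margins)
    produced = 0

    def fill(row: int, remaining_cols: np.ndarray, rows_acc: list):
        nonlocal produced
        if row == n_rows - 1:
            produced += 1
            if produced > limit:
                raise OverflowError
            yield rows_acc + [remaining_cols.copy()]
            return
        total = row_margins[row]
        cols = len(remaining_cols)

        def fill_row(col: int, left: int, row_acc: list):
            if col == cols - 1:
                if left <= remaining_cols[col]:
                    yield row_acc + [left]
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                yield from fill_row(col + 1, left - v, row_acc + [v])

        for row_vals in fill_row(0, total, []):
            arr = np.array(row_vals, dtype=np.int64)
            yield from fill(row + 1, remaining_cols - arr, rows_acc + [arr])

    yield from fill(0, col_margins.copy(), [])


def fisher_exact_rxc(
    table: np.ndarray,
    seed: Optional[int] = None,
    mc_resamples: int = MC_RESAMPLES,
    max_total: int = EXACT_ENUMERATION_MAX_TOTAL,
) -> tuple[float, str]:
    """Two-sided Fisher exact p for an r x c table.

    Exact Freeman-Halton enumeration when the table total is at most
    `max_total` (with a hard cap on enumerated tables); otherwise a seeded
    Monte-Carlo estimate over tables drawn with the observed margins.
    Returns (p, method).
    """
    table = np.asarray(table, dtype=np.int64)
    row_margins = table.sum(axis=1)
    col_margins = table.sum(axis=0)
    obs_lp = _table_logprob(table, row_margins, col_margins)
    tol = 1e-9
    if table.sum() <= max_total:
        try:
            p = 0.0
            for cand in _enumerate_tables(row_margins, col_margins, limit=5_000_000):
                lp = _table_logprob(np.array(cand), row_margins, col_margins)
                if lp <= obs_lp + tol:
                    p += math.exp(lp)
            return min(p, 1.0), "exact"
        except OverflowError:
            pass
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_margins, col_margins)
    draws = dist.rvs(mc_resamples, random_state=rng)
    lps = (
        gammaln(row_margins + 1).sum()
        + gammaln(col_margins + 1).sum()
        - gammaln(row_margins.sum() + 1)
        - gammaln(draws + 1).sum(axis=(1, 2))
    )
    hits = int((lps <= obs_lp + tol).sum())
    return (hits + 1) / (mc_resamples + 1), "monte_carlo"


def contingency_test(
    table: np.ndarray, seed: Optional[int] = None
) -> tuple[str, float]:
    """Apply the test-selection rule and return (test name, two-sided p)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return "degenerate", 1.0
    test = select_test(table)
    if test == "pearson_chi2":
        res = stats.chi2_contingency(table, correction=False)
        return test, float(res.pvalue)
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return test, float(p)
    p, _ = fisher_exact_rxc(table, seed=seed)
    return test, p


def compare_populations(
    tables: Sequence[BreedFrequencyTable],
    gene_id: str,
    n_breeds_tested: int = DEFAULT_N_BREEDS,
    units: str = "chromosomes",
    seed: Optional[int] = None,
    followup: bool = True,
) -> ComparisonResult:
    """Test whether a gene's allele distribution differs between the given
    same-breed subpopulations, at alpha = 0.05 / n_breeds_tested."""
    if len(tables) < 2:
        raise ValueError("at least two subpopulations are required")
    breed = tables[0].breed
    matrix, pops, classes, warnings = build_contingency(tables, gene_id, units)
    alpha = 0.05 / n_breeds_tested
    if len(pops) < 2:
        warnings.append("fewer than two populations with data; untestable")
        return ComparisonResult(
            breed, gene_id, pops, classes, matrix, "none", float("nan"),
            alpha, False, status="untestable", warnings=warnings,
        )
    test, p = contingency_test(matrix, seed=seed)
    status = "degenerate" if test == "degenerate" else "ok"
    significant = status == "ok" and p <= alpha
    result = ComparisonResult(
        breed, gene_id, pops, classes, matrix, test, p, alpha, significant,
        status=status, warnings=warnings,
    )
    if followup and significant and len(pops) > 2:
        result.pairwise = pairwise_followup(tables, gene_id, units=units, seed=seed)
    return result


def pairwise_followup(
    tables: Sequence[BreedFrequencyTable],
    gene_id: str,
    n_subpopulations: Optional[int] = None,
    units: str = "chromosomes",
    seed: Optional[int] = None,
) -> list[PairwiseResult]:
    """All pairwise tests at alpha = 0.05 / n_subpopulations."""
    matrix, pops, _, _ = build_contingency(tables, gene_id, units)
    n = n_subpopulations if n_subpopulations is not None else len(pops)
    alpha = 0.05 / n
    results = []
    for i, j in itertools.combinations(range(len(pops)), 2):
        pair = matrix[[i, j], :]
        pair = pair[:, pair.sum(axis=0) > 0]
        test, p = contingency_test(pair, seed=seed)
        results.append(
            PairwiseResult(pops[i], pops[j], test, p, alpha, p <= alpha)
        )
    return results
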