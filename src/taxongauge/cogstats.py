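"""Per-category replicon comparison of COG functional annotations.

Given protein counts per COG category for each replicon (category
assignment itself happens upstream; multi-category proteins contribute
one count per assigned category), every category is tested between a
pair of replicons with a two-sided Fisher exact test on the 2x2 table
(in-category vs not, replicon A vs B), and p-values are adjusted by
Benjamini-Hochberg step-up within the replicon pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

logger = logging.getLogger(__name__)


@dataclass
class COGCountTable:
    """replicon id -> {category letter -> protein count}."""

    counts: dict[str, dict[str, int]]

    def total(self, replicon: str) -> int:
        return sum(self.counts[replicon].values())

    def categories(self, *replicons: str) -> list[str]:
        cats: set[str] = set()
        for rep in replicons:
            cats.update(c for c, n in self.counts[rep].items() if n > 0)
        return sorted(cats)


@dataclass
class EnrichmentResult:
    category: str
    replicon_a: str
    replicon_b: str
    table: tuple[int, int, int, int]  # (a in-cat, a not, b in-cat, b not)
    p_value: float
    q_value: float = float("nan")
    significant_05: bool = False
    significant_01: bool = False


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness follows the minimum-likelihood rule (tables with
    hypergeometric probability <= that of the observed table, at fixed
    margins).  Any zero margin gives p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        logger.debug("zero margin in table (%d,%d,%d,%d): p = 1", a, b, c, d)
        return 1.0
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order restored.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_replicons(
    table: COGCountTable,
    pair: tuple[str, str],
    alpha_star: float = 0.05,
    alpha_double_star: float = 0.01,
) -> list[EnrichmentResult]:
    """One Fisher test per category between two replicons, BH-adjusted.

    The FDR family is the set of categories present in either replicon of
    this pair (stars in a per-pair comparison figure are per-pair).
    """
    rep_a, rep_b = pair
    for rep in pair:
        if rep not in table.counts:
            raise ValueError(f"replicon {rep!r} not present in count table")
    total_a, total_b = table.total(rep_a), table.total(rep_b)
    results = []
    for category in table.categories(rep_a, rep_b):
        in_a = table.counts[rep_a].get(category, 0)
        in_b = table.counts[rep_b].get(category, 0)
        tab = (in_a, total_a - in_a, in_b, total_b - in_b)
        results.append(EnrichmentResult(category, rep_a, rep_b, tab, fisher_exact_2x2(*tab)))
    q_values = bh_adjust([r.p_value for r in results])
    for result, q in zip(results, q_values):
        result.q_value = float(q)
        result.significant_05 = q < alpha_star
        result.significant_01 = q < alpha_double_star
    return results
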