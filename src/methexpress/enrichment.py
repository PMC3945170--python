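"""Hypergeometric over-representation analysis by category.

For a query of ``n`` genes drawn from a background universe of ``N``
objects, a category containing ``K`` background objects and ``actual``
query hits gets

    expected = n*K/N
    ratio    = actual / expected
    z        = (actual - expected) / sqrt(n*(K/N)*(1-K/N)*(N-n)/(N-1))
    p        = upper-tail hypergeometric P(X >= actual)
               (lower tail P(X <= actual) for depleted categories, z < 0)

Category annotations are user-supplied (a plain gene→category map); no
ontology or protein-class database is bundled.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy import stats

__all__ = ["ora", "ora_counts", "intersect_rank"]


def ora_counts(actual: int, K: int, n: int, N: int) -> dict:
    """Enrichment arithmetic for one category from its four counts."""
    if not (0 <= actual <= min(K, n)):
        raise ValueError(f"actual={actual} outside [0, min(K={K}, n={n})]")
    if n == 0:
        raise ValueError("query size n must be positive")
    if K > N or n > N:
        raise ValueError("category and query must fit inside the background")
    expected = n * K / N
    sd = math.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
    z = (actual - expected) / sd if sd > 0 else math.nan
    p_over = float(stats.hypergeom.sf(actual - 1, N, K, n))
    p_under = float(stats.hypergeom.cdf(actual, N, K, n))
    return {
        "actual": actual, "K": K, "n": n, "N": N,
        "expected": expected,
        "ratio": actual / expected if expected > 0 else math.inf,
        "z": z,
        "p_over": p_over,
        "p_under": p_under,
        "p": p_over if (math.isnan(z) or z >= 0) else p_under,
        "pct_in_dataset": 100.0 * actual / n,
        "pct_in_category": 100.0 * actual / K if K else math.nan,
        "pct_category_in_background": 100.0 * K / N,
    }


def ora(query, categories: pd.DataFrame, background_size: int,
        skipped: list | None = None) -> pd.DataFrame:
    """Over-representation analysis of a query gene set.

    ``categories`` is a two-column frame (``gene``, ``category``); its
    genes define the annotated part of the background and a gene may
    belong to several categories.  ``background_size`` is the size of the
    full universe (which may exceed the annotated genes).  Empty
    categories are skipped (ids collected into ``skipped`` when given).
    Rows come back sorted by p then category.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    rows = []
    for category, sub in categories.groupby("category", sort=True):
        members = set(sub["gene"])
        K = len(members)
        if K == 0:
            if skipped is not None:
                skipped.append(category)
            continue
        stats_row = ora_counts(len(query & members), K, len(query),
                               background_size)
        rows.append({"category": category, **stats_row})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(["p", "category"], kind="stable").reset_index(drop=True)


def intersect_rank(enrich_a: pd.DataFrame, enrich_b: pd.DataFrame) -> pd.DataFrame:
    """Rank categories shared by two enrichment results.

    Keeps categories present in both tables and orders them by the worse
    (larger) of the two p-values, ascending — the most concordantly
    enriched terms first.  Empty intersection yields an empty frame.
    """
    shared = enrich_a.merge(enrich_b, on="category", suffixes=("_a", "_b"))
    if shared.empty:
        return pd.DataFrame(columns=["category", "p_a", "p_b", "p_worse"])
    shared["p_worse"] = shared[["p_a", "p_b"]].max(axis=1)
    shared = shared.sort_values(["p_worse", "category"], kind="stable")
    return shared.reset_index(drop=True)
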