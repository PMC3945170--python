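"""Methylation–expression matching and correlation-sign tabulation.

A *matched pair* is a (differentially methylated CpG, differentially
expressed transcript) link taken from the manifest.  Each pair carries
the CpG's Δβ direction and both context labels, plus the Spearman rank
correlation ρ between the CpG's β-values and the transcript's expression
across samples.  The sign of ρ classifies the pair: positive means
hypermethylation with over-expression or hypomethylation with
under-expression; negative the reverse.  Pairs are then cross-tabulated
by context, and each stratum's negative fraction is compared to the
overall negative fraction with a one-sample two-tailed z test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GENE_CONTEXTS, ISLAND_CONTEXTS, ProbeRecord

__all__ = [
    "match",
    "classify_correlation",
    "add_correlations",
    "tabulate_by_context",
    "proportion_test",
]


def match(dm: pd.DataFrame, de_transcripts, records: list[ProbeRecord]) -> pd.DataFrame:
    """Link DM CpGs to DE transcripts through the manifest gene links.

    One output row per (CpG, transcript) link whose transcript is
    differentially expressed; a CpG linked to several DE transcripts
    yields several pairs, and a CpG linked to none yields no pair.
    """
    de_set = set(de_transcripts)
    by_probe = {rec.probe_id: rec for rec in records}
    rows = []
    for _, dm_row in dm.iterrows():
        rec = by_probe.get(dm_row["probe_id"])
        if rec is None:
            continue
        for transcript_id, gene_context in rec.gene_links:
            if transcript_id in de_set:
                rows.append({
                    "cpg_id": rec.probe_id,
                    "transcript_id": transcript_id,
                    "direction": dm_row["direction"],
                    "delta_beta": dm_row["delta_beta"],
                    "gene_context": gene_context,
                    "island_context": rec.island_context,
                })
    columns = ["cpg_id", "transcript_id", "direction", "delta_beta",
               "gene_context", "island_context"]
    return pd.DataFrame(rows, columns=columns)


def classify_correlation(beta_row, expr_row) -> tuple[float, str]:
    """Spearman ρ (average ranks on ties) and its sign class.

    Samples where either series is missing are dropped pairwise.  A
    constant series, fewer than 3 paired observations, or ρ = 0 give the
    class ``excluded`` with ρ = NaN (or 0).
    """
    b = np.asarray(beta_row, dtype=float)
    e = np.asarray(expr_row, dtype=float)
    ok = np.isfinite(b) & np.isfinite(e)
    b, e = b[ok], e[ok]
    if b.size < 3 or np.all(b == b[0]) or np.all(e == e[0]):
        return math.nan, "excluded"
    rho = float(stats.spearmanr(b, e).statistic)
    if math.isnan(rho) or rho == 0:
        return rho, "excluded"
    return rho, "positive" if rho > 0 else "negative"


def add_correlations(pairs: pd.DataFrame, beta: pd.DataFrame,
                     expr: pd.DataFrame, probe_map: pd.DataFrame,
                     samples: list[str],
                     present: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach ρ and corr_class to every matched pair.

    Expression rows are looked up through the probe→transcript map (the
    collapsed DE representative probe per transcript); β rows are masked
    to present samples when a presence mask is given.
    """
    rep = probe_map.set_index("transcript_id")["probe_id"]
    masked = beta.where(present.reindex_like(beta)) if present is not None else beta
    rhos, classes = [], []
    for _, row in pairs.iterrows():
        b = masked.loc[row["cpg_id"], samples]
        e = expr.loc[rep[row["transcript_id"]], samples]
        rho, cls = classify_correlation(b, e)
        rhos.append(rho)
        classes.append(cls)
    out = pairs.copy()
    out["rho"] = rhos
    out["corr_class"] = classes
    return out


def proportion_test(n_neg: int, n_total: int, p0: float) -> tuple[float, float]:
    """One-sample two-tailed z test of a stratum's negative fraction.

    ``z = (p̂ − p0) / sqrt(p0(1−p0)/n)`` with ``p = 2Φ(−|z|)``; no
    continuity correction.  Degenerate reference fractions (p0 of 0 or 1)
    give p = 1 when the stratum matches exactly and an infinite z with
    p = 0 otherwise.
    """
    if n_total < 1:
        raise ValueError("stratum must contain at least one pair")
    p_hat = n_neg / n_total
    if p0 <= 0 or p0 >= 1:
        if p_hat == p0:
            return 0.0, 1.0
        return math.copysign(math.inf, p_hat - p0), 0.0
    z = (p_hat - p0) / math.sqrt(p0 * (1 - p0) / n_total)
    return z, 2.0 * float(stats.norm.sf(abs(z)))


def tabulate_by_context(pairs: pd.DataFrame, stratify: str = "gene") -> pd.DataFrame:
    """Cross-tabulate classified pairs by context with proportion tests.

    One row per stratum in canonical context order plus an ``Overall``
    row; excluded pairs are dropped before counting.  Each (CpG,
    transcript) link counts as one unit.  The ratio column is
    ``n_neg / n_pos`` (``inf`` when a stratum has no positive pairs);
    z and p compare the stratum's negative fraction with the fixed
    overall negative fraction.
    """
    if stratify == "gene":
        column, order = "gene_context", GENE_CONTEXTS
    elif stratify == "island":
        column, order = "island_context", ISLAND_CONTEXTS
    elif stratify == "direction":
        column, order = "direction", ("hypo", "hyper")
    else:
        raise ValueError("stratify must be 'gene', 'island' or 'direction'")
    usable = pairs[pairs["corr_class"].isin(["positive", "negative"])]
    total_pos = int((usable["corr_class"] == "positive").sum())
    total_neg = int((usable["corr_class"] == "negative").sum())
    total = total_pos + total_neg
    p0 = total_neg / total if total else math.nan
    rows = []
    for stratum in order:
        sub = usable[usable[column] == stratum]
        n_pos = int((sub["corr_class"] == "positive").sum())
        n_neg = int((sub["corr_class"] == "negative").sum())
        n = n_pos + n_neg
        if n == 0:
            z, p = math.nan, math.nan
        else:
            z, p = proportion_test(n_neg, n, p0)
        rows.append({
            "stratum": stratum, "n_total": n, "n_pos": n_pos, "n_neg": n_neg,
            "ratio_neg_pos": (n_neg / n_pos) if n_pos else math.inf,
            "z": z, "p_two_tailed": p,
        })
    rows.append({
        "stratum": "Overall", "n_total": total, "n_pos": total_pos,
        "n_neg": total_neg,
        "ratio_neg_pos": (total_neg / total_pos) if total_pos else math.inf,
        "z": 0.0 if total else math.nan, "p_two_tailed": 1.0 if total else math.nan,
    })
    return pd.DataFrame(rows)
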