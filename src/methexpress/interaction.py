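"""Per-gene two-factor ANOVA prioritization of methylation-driven genes.

For each differentially expressed transcript, the β-values of all its
matched, differentially methylated CpGs — one observation per
(CpG, sample) — are modelled as

    β ~ status + location + status:location

where *status* is the CpG's Δβ direction (hypo/hyper) and *location* its
context, under two taxonomies: relative to the transcript (TSS1500,
TSS200, 5'UTR, first exon, body, 3'UTR) and relative to the closest CGI
(island, shore, open sea).  The interaction F is the extra-sum-of-squares
comparison of the full (cell-means) model against the additive model,
with the interaction degrees of freedom taken as the rank difference of
the two design matrices so that arbitrary unbalanced or empty-cell
patterns are handled.  A gene is testable only when both factors have at
least two observed levels *and* the interaction is estimable (the
status×location incidence graph contains a cycle); the two taxonomies
are Benjamini–Hochberg-adjusted as separate families over testable genes
and a gene is called significant when either adjusted p falls below α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "AnovaResult",
    "UntestableInteraction",
    "interaction_anova",
    "run_interaction_analysis",
]


class UntestableInteraction(ValueError):
    """The interaction is not estimable for this gene.

    ``reason`` is one of ``single_factor_level``,
    ``interaction_inestimable``, ``too_few_cpgs`` or ``no_residual_df``.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: int
    df_resid: int
    p: float
    sse_full: float
    sse_additive: float
    n_obs: int
    cells: dict


def _dummy_columns(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummies (first level dropped), levels sorted."""
    levels = sorted(set(labels.tolist()))
    return np.column_stack(
        [(labels == lv).astype(float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((labels.size, 0))


def interaction_anova(y, status, location, df_lost: int = 0) -> AnovaResult:
    """Extra-sum-of-squares F test of the status×location interaction.

    ``y`` are per-(CpG, sample) β-values; ``status`` and ``location``
    the CpG-level factor labels, repeated per observation.  Raises
    :class:`UntestableInteraction` when the interaction has no testable
    degrees of freedom.  A perfect fit of the full model (zero residual
    sum of squares) with a worse additive fit yields ``F = inf, p = 0``.

    ``df_lost`` subtracts degrees of freedom consumed by any adjustment
    applied to ``y`` upstream (e.g. per-CpG phenotype centering) so the
    residual mean square stays unbiased.
    """
    y = np.asarray(y, dtype=float)
    status = np.asarray(status, dtype=object)
    location = np.asarray(location, dtype=object)
    ok = np.isfinite(y)
    y, status, location = y[ok], status[ok], location[ok]
    n = y.size
    if len(set(status.tolist())) < 2 or len(set(location.tolist())) < 2:
        raise UntestableInteraction("single_factor_level")

    cells = pd.Series(range(n)).groupby([pd.Series(status), pd.Series(location)],
                                        sort=True).groups
    n_cells = len(cells)
    df_resid = n - n_cells - df_lost
    if df_resid < 1:
        raise UntestableInteraction("no_residual_df")

    # Full model = one mean per observed cell.
    sse_full = 0.0
    cell_counts = {}
    for key, idx in cells.items():
        vals = y[np.fromiter(idx, dtype=int)]
        sse_full += float(((vals - vals.mean()) ** 2).sum())
        cell_counts[key] = vals.size

    X_add = np.column_stack([np.ones(n), _dummy_columns(status),
                             _dummy_columns(location)])
    rank_add = int(np.linalg.matrix_rank(X_add))
    df_num = n_cells - rank_add
    if df_num < 1:
        raise UntestableInteraction("interaction_inestimable")

    coef, *_ = np.linalg.lstsq(X_add, y, rcond=None)
    resid = y - X_add @ coef
    sse_add = float(resid @ resid)
    ss_int = max(sse_add - sse_full, 0.0)

    if sse_full <= 1e-300:
        F = math.inf if ss_int > 0 else 0.0
        p = 0.0 if ss_int > 0 else 1.0
    else:
        F = (ss_int / df_num) / (sse_full / df_resid)
        p = float(stats.f.sf(F, df_num, df_resid))
    return AnovaResult(F=F, df_num=df_num, df_resid=df_resid, p=p,
                       sse_full=sse_full, sse_additive=sse_add, n_obs=n,
                       cells=cell_counts)


def _gene_observations(cpg_ids, contexts, beta, samples, present, group_idx):
    """Long (y, location, df_lost) vectors for one gene under one taxonomy.

    When ``group_idx`` (per-sample phenotype partition) is given, each
    CpG's values are centered within phenotype and re-anchored at the
    CpG's pooled mean: the between-phenotype shift — already encoded by
    the status factor — leaves the residual, while every (status,
    location) cell mean is unchanged.  ``df_lost`` counts the degrees of
    freedom those per-(CpG, phenotype) means consumed.
    """
    ys, locs = [], []
    df_lost = 0
    for cpg, ctx in zip(cpg_ids, contexts):
        row = beta.loc[cpg, samples]
        if present is not None:
            row = row.where(present.loc[cpg, samples])
        vals = row.to_numpy(dtype=float)
        if group_idx is not None:
            finite = np.isfinite(vals)
            pooled = vals[finite].mean() if finite.any() else math.nan
            centered = vals.copy()
            n_groups = 0
            for idx in group_idx:
                sel = idx[finite[idx]]
                if sel.size:
                    centered[sel] = vals[sel] - vals[sel].mean() + pooled
                    n_groups += 1
            vals = centered
            df_lost += max(n_groups - 1, 0)
        ys.append(vals)
        locs.append(np.repeat(ctx, vals.size))
    return np.concatenate(ys), np.concatenate(locs), df_lost


def run_interaction_analysis(
    pairs: pd.DataFrame,
    beta: pd.DataFrame,
    samples: list[str],
    present: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_cpgs: int = 2,
    sample_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run the interaction ANOVA for every gene with matched CpGs.

    ``pairs`` is the matched-pair table (one row per CpG–transcript
    link); only differentially methylated CpGs appear there, so every
    observation has a status.  Returns one row per gene with raw and
    BH-adjusted p under both taxonomies, the minimum raw p (the value
    reported per gene), and the significance call (either adjusted
    p < ``alpha``).  Genes untestable under both taxonomies carry the
    reason instead.

    ``sample_groups`` maps sample id → phenotype; when supplied, each
    CpG's observations are centered within phenotype (df-corrected)
    before the two-factor ANOVA, which keeps the F reference calibrated:
    without it the residual mean square absorbs the between-phenotype β
    shift that cancels in cell means, making the test conservative.
    """
    group_idx = None
    if sample_groups is not None:
        by_group: dict[str, list[int]] = {}
        for j, s in enumerate(samples):
            by_group.setdefault(sample_groups[s], []).append(j)
        group_idx = [np.asarray(v, dtype=int) for v in by_group.values()]
    results = []
    for gene, sub in pairs.groupby("transcript_id", sort=True):
        sub = sub.drop_duplicates(subset="cpg_id")
        record = {
            "gene_id": gene,
            "n_cpgs": len(sub),
            "p_gene_ctx": math.nan, "p_island_ctx": math.nan,
            "F_gene_ctx": math.nan, "F_island_ctx": math.nan,
            "untestable_gene_ctx": "", "untestable_island_ctx": "",
        }
        if len(sub) < min_cpgs:
            record["untestable_gene_ctx"] = "too_few_cpgs"
            record["untestable_island_ctx"] = "too_few_cpgs"
            results.append(record)
            continue
        status = sub["direction"].to_numpy(dtype=object)
        for taxonomy, column in (("gene_ctx", "gene_context"),
                                 ("island_ctx", "island_context")):
            y, loc, df_lost = _gene_observations(sub["cpg_id"], sub[column], beta,
                                                 samples, present, group_idx)
            st = np.repeat(status, [len(samples)] * len(sub))
            try:
                res = interaction_anova(y, st, loc, df_lost=df_lost)
                record[f"p_{taxonomy}"] = res.p
                record[f"F_{taxonomy}"] = res.F
            except UntestableInteraction as exc:
                record[f"untestable_{taxonomy}"] = exc.reason
        results.append(record)
    table = pd.DataFrame(results)
    if table.empty:
        return pd.DataFrame(columns=[
            "gene_id", "n_cpgs", "F_gene_ctx", "F_island_ctx", "p_gene_ctx",
            "p_island_ctx", "p_min", "p_adj_gene_ctx", "p_adj_island_ctx",
            "significant", "untestable_gene_ctx", "untestable_island_ctx"])
    for taxonomy in ("gene_ctx", "island_ctx"):
        adj = np.full(len(table), math.nan)
        testable = table[f"p_{taxonomy}"].notna().to_numpy()
        if testable.any():
            adj[testable] = bh_adjust(table.loc[testable, f"p_{taxonomy}"].to_numpy())
        table[f"p_adj_{taxonomy}"] = adj
    table["p_min"] = table[["p_gene_ctx", "p_island_ctx"]].min(axis=1)
    table["significant"] = (
        table[["p_adj_gene_ctx", "p_adj_island_ctx"]].min(axis=1) < alpha
    ).fillna(False)
    cols = ["gene_id", "n_cpgs", "F_gene_ctx", "F_island_ctx", "p_gene_ctx",
            "p_island_ctx", "p_min", "p_adj_gene_ctx", "p_adj_island_ctx",
            "significant", "untestable_gene_ctx", "untestable_island_ctx"]
    return table[cols]
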