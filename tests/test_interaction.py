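"""Status × location interaction ANOVA: oracles, invariances, bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from methexpress.interaction import (UntestableInteraction, interaction_anova,
                                     run_interaction_analysis)


def pinv_least_squares_oracle(y, status, location):
    """Independent route: explicit dummy designs solved by pseudoinverse."""
    y = np.asarray(y, float)
    s_levels = sorted(set(status))
    l_levels = sorted(set(location))
    S = np.column_stack([[s == lv for s in status] for lv in s_levels]).astype(float)
    L = np.column_stack([[l == lv for l in location] for lv in l_levels]).astype(float)
    inter = np.column_stack([S[:, i] * L[:, j]
                             for i in range(S.shape[1])
                             for j in range(L.shape[1])])
    X_add = np.column_stack([np.ones(len(y)), S[:, 1:], L[:, 1:]])
    X_full = np.column_stack([X_add, inter])

    def sse(X):
        beta = np.linalg.pinv(X) @ y
        r = y - X @ beta
        return float(r @ r)

    sse_add, sse_full = sse(X_add), sse(X_full)
    df_num = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_add)
    df_resid = len(y) - np.linalg.matrix_rank(X_full)
    if df_num == 0:
        return None
    F = ((sse_add - sse_full) / df_num) / (sse_full / df_resid)
    return F, df_num, df_resid


def closed_form_balanced_f(y, status, location):
    """Classical two-way interaction F from cell means (balanced designs)."""
    df = pd.DataFrame({"y": y, "s": status, "l": location})
    grand = df["y"].mean()
    cell = df.groupby(["s", "l"])["y"].mean()
    row = df.groupby("s")["y"].mean()
    col = df.groupby("l")["y"].mean()
    r = df.groupby(["s", "l"]).size().iloc[0]
    ss_int = r * sum((cell[s, l] - row[s] - col[l] + grand) ** 2
                     for s, l in cell.index)
    a, b = row.size, col.size
    resid = df["y"].to_numpy() - cell.loc[list(zip(df["s"], df["l"]))].to_numpy()
    sse = float((resid ** 2).sum())
    df_int = (a - 1) * (b - 1)
    df_resid = len(df) - a * b
    return (ss_int / df_int) / (sse / df_resid), df_int, df_resid


def _random_design(rng, n_status=2, n_location=3, n=24):
    status = rng.choice([f"s{i}" for i in range(n_status)], size=n)
    location = rng.choice([f"l{i}" for i in range(n_location)], size=n)
    y = rng.normal(size=n)
    return y, status, location


class TestInteractionAnova:
    def test_single_status_level_untestable(self):
        with pytest.raises(UntestableInteraction, match="single_factor_level"):
            interaction_anova(np.arange(8.0), ["hyper"] * 8,
                              ["Body", "TSS200"] * 4)

    def test_perfect_interaction_zero_noise(self):
        # 2x2 balanced cells, means 0.2/0.2/0.2/0.6, two CpGs x 4 samples per cell
        means = {("hypo", "Island"): 0.2, ("hypo", "Body"): 0.2,
                 ("hyper", "Island"): 0.2, ("hyper", "Body"): 0.6}
        y, st_, loc = [], [], []
        for (s, l), m in means.items():
            y += [m] * 8
            st_ += [s] * 8
            loc += [l] * 8
        res = interaction_anova(np.array(y), st_, loc)
        assert math.isinf(res.F) and res.p == 0.0

    def test_matches_pseudoinverse_oracle_on_random_designs(self):
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(60):
            y, status, location = _random_design(rng, n=int(rng.integers(12, 31)))
            oracle = None
            try:
                res = interaction_anova(y, status, location)
            except UntestableInteraction:
                res = None
            oracle = pinv_least_squares_oracle(y, status, location)
            if res is None:
                assert oracle is None or len(set(status)) < 2 \
                    or len(set(location)) < 2
                continue
            F, df_num, df_resid = oracle
            assert res.F == pytest.approx(F, rel=1e-9)
            assert (res.df_num, res.df_resid) == (df_num, df_resid)
            checked += 1
        assert checked >= 30

    def test_balanced_design_equals_closed_form(self):
        rng = np.random.default_rng(10)
        status = np.repeat(["hypo", "hyper"], 18)
        location = np.tile(np.repeat(["I", "S", "O"], 6), 2)
        y = rng.normal(size=36)
        res = interaction_anova(y, status, location)
        F, df_int, df_resid = closed_form_balanced_f(y, status, location)
        assert res.F == pytest.approx(F, abs=1e-10, rel=1e-10)
        assert (res.df_num, res.df_resid) == (df_int, df_resid)

    def test_invariant_to_level_relabeling(self):
        rng = np.random.default_rng(12)
        y, status, location = _random_design(rng, n=30)
        res = interaction_anova(y, status, location)
        relabeled = interaction_anova(
            y, np.where(status == "s0", "zz", "aa"),
            np.char.add("loc_", location.astype(str)))
        assert relabeled.F == pytest.approx(res.F)
        assert relabeled.p == pytest.approx(res.p)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(13)
        y, status, location = _random_design(rng, n=30)
        res = interaction_anova(y, status, location)
        shifted = interaction_anova(y + 5.0, status, location)
        assert shifted.F == pytest.approx(res.F, rel=1e-9)

    def test_chain_pattern_inestimable(self):
        # statuses and locations form an acyclic incidence pattern:
        # the additive model saturates the cells, leaving 0 interaction df
        y = np.random.default_rng(14).normal(size=24)
        status = ["hypo"] * 12 + ["hyper"] * 12
        location = ["TSS200"] * 6 + ["TSS1500"] * 6 + ["Body"] * 12
        with pytest.raises(UntestableInteraction,
                           match="interaction_inestimable"):
            interaction_anova(y, status, location)

    def test_df_lost_reduces_residual_df(self):
        rng = np.random.default_rng(15)
        y, status, location = _random_design(rng, n=30)
        base = interaction_anova(y, status, location)
        adj = interaction_anova(y, status, location, df_lost=5)
        assert adj.df_resid == base.df_resid - 5


class TestRunInteractionAnalysis:
    def _inputs(self):
        samples = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(21)
        cpgs, rows = [], []
        # gene A: estimable 2x2 pattern; gene B: one status only; gene C: 1 CpG
        layout = [("A", "hypo", "Island"), ("A", "hypo", "Shore"),
                  ("A", "hyper", "Island"), ("A", "hyper", "Shore"),
                  ("B", "hyper", "Island"), ("B", "hyper", "Shore"),
                  ("C", "hypo", "Island")]
        for i, (gene, direction, island) in enumerate(layout):
            cpg = f"cg{i}"
            cpgs.append(cpg)
            rows.append({"cpg_id": cpg, "transcript_id": gene,
                         "direction": direction, "gene_context": "Body",
                         "island_context": island})
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, size=(len(cpgs), 8)),
                            index=cpgs, columns=samples)
        return pd.DataFrame(rows), beta, samples

    def test_untestable_genes_not_in_bh_family(self):
        pairs, beta, samples = self._inputs()
        out = run_interaction_analysis(pairs, beta, samples)
        by_gene = out.set_index("gene_id")
        assert by_gene.loc["B", "untestable_island_ctx"] == "single_factor_level"
        assert by_gene.loc["C", "untestable_island_ctx"] == "too_few_cpgs"
        assert math.isnan(by_gene.loc["B", "p_adj_island_ctx"])
        # family of size 1 -> adjusted equals raw for the only testable gene
        assert by_gene.loc["A", "p_adj_island_ctx"] == pytest.approx(
            by_gene.loc["A", "p_island_ctx"])
        # gene context has a single location level everywhere here
        assert by_gene.loc["A", "untestable_gene_ctx"] == "single_factor_level"

    def test_p_min_is_min_of_available_taxonomies(self):
        pairs, beta, samples = self._inputs()
        out = run_interaction_analysis(pairs, beta, samples).set_index("gene_id")
        assert out.loc["A", "p_min"] == pytest.approx(out.loc["A", "p_island_ctx"])

    def test_phenotype_centering_preserves_cell_means_and_f_signal(self):
        # strong planted interaction: centering must not remove the signal
        samples = [f"c{i}" for i in range(6)] + [f"t{i}" for i in range(6)]
        groups = {s: ("ctrl" if s.startswith("c") else "case") for s in samples}
        rows, data = [], []
        cells = [("hypo", "Island", 0.85, -0.4), ("hypo", "Shore", 0.85, -0.4),
                 ("hyper", "Island", 0.10, 0.4), ("hyper", "Shore", 0.40, 0.4)]
        rng = np.random.default_rng(31)
        cpgs = []
        for i, (direction, island, base, eff) in enumerate(cells * 2):
            cpg = f"cg{i}"
            cpgs.append(cpg)
            rows.append({"cpg_id": cpg, "transcript_id": "G",
                         "direction": direction, "gene_context": "Body",
                         "island_context": island})
            vals = np.concatenate([
                rng.normal(base, 0.01, 6), rng.normal(base + eff, 0.01, 6)])
            data.append(vals)
        beta = pd.DataFrame(np.vstack(data), index=cpgs, columns=samples)
        raw = run_interaction_analysis(pd.DataFrame(rows), beta, samples)
        centered = run_interaction_analysis(pd.DataFrame(rows), beta, samples,
                                            sample_groups=groups)
        assert centered.loc[0, "p_island_ctx"] < 1e-6
        assert centered.loc[0, "F_island_ctx"] > raw.loc[0, "F_island_ctx"]
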