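"""Two-group fits, empirical-Bayes moderation, BH and the Δβ caller."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methexpress.differential import (bh_adjust, call_dm,
                                      collapse_to_transcripts,
                                      estimate_eb_params, fit_two_group,
                                      moderate)
from methexpress.preprocess import SampleDesign


def bh_brute_force(p):
    """Literal step-up definition: adj(i) = min_{k>=i} m*p(k)/k, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[k - 1]] / k for k in range(rank_pos, m + 1)]
        out[idx] = min(1.0, min(candidates))
    return out


def _frame(ctrl, case):
    cols = {f"c{i}": [v] for i, v in enumerate(ctrl)}
    cols.update({f"t{i}": [v] for i, v in enumerate(case)})
    return pd.DataFrame(cols), [f"t{i}" for i in range(len(case))], \
        [f"c{i}" for i in range(len(ctrl))]


class TestFitTwoGroup:
    def test_constant_groups(self):
        expr, case, ctrl = _frame([1, 1, 1], [2, 2, 2])
        fit = fit_two_group(expr, case, ctrl)
        assert fit["effect"].iloc[0] == 1.0
        assert fit["s2"].iloc[0] == 0.0
        assert fit["df_resid"].iloc[0] == 4

    def test_hand_computed_pooled_variance(self):
        expr, case, ctrl = _frame([0, 2], [1, 3])
        fit = fit_two_group(expr, case, ctrl)
        assert fit["effect"].iloc[0] == 1.0
        assert fit["s2"].iloc[0] == pytest.approx(2.0)
        assert fit["df_resid"].iloc[0] == 2

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(50, 12))
        cols = [f"s{i}" for i in range(12)]
        expr = pd.DataFrame(data, columns=cols)
        perm = cols[:6][::-1] + cols[6:][::-1]
        f1 = fit_two_group(expr, cols[6:], cols[:6])
        f2 = fit_two_group(expr, perm[6:], perm[:6])
        pd.testing.assert_frame_equal(f1, f2)


class TestModerate:
    def _fits(self, n=200, seed=0, df=10):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "effect": rng.normal(size=n),
            "s2": rng.chisquare(df, n) / df,
            "df_resid": df, "n_case": 6, "n_control": 6,
        })

    def test_d0_zero_equals_ordinary_t(self):
        fits = self._fits()
        _, out = moderate(fits, d0=0)
        t_ord = fits["effect"] / np.sqrt(fits["s2"] * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(out["t_mod"], t_ord)

    def test_d0_infinite_is_z_form(self):
        fits = self._fits()
        params, out = moderate(fits, d0=math.inf)
        t_inf = fits["effect"] / np.sqrt(params.s0_sq * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(out["t_mod"], t_inf)

    def test_t_between_limits(self):
        fits = self._fits(seed=3)
        p0, out0 = moderate(fits, d0=0)
        pinf, outinf = moderate(fits, d0=math.inf)
        params, out = moderate(fits)
        lo = np.minimum(np.abs(out0["t_mod"]), np.abs(outinf["t_mod"]))
        hi = np.maximum(np.abs(out0["t_mod"]), np.abs(outinf["t_mod"]))
        assert ((lo - 1e-12 <= np.abs(out["t_mod"]))
                & (np.abs(out["t_mod"]) <= hi + 1e-12)).all()

    def test_hyperparameter_recovery(self):
        rng = np.random.default_rng(11)
        d0, s0_sq, df = 4.0, 2.0, 10
        sigma2 = s0_sq * d0 / rng.chisquare(d0, 5000)
        s2 = sigma2 * rng.chisquare(df, 5000) / df
        params = estimate_eb_params(s2, df)
        assert 3.0 <= params.d0 <= 5.0
        assert 1.8 <= params.s0_sq <= 2.2

    def test_identical_variances_fall_back_to_infinite_prior(self):
        fits = pd.DataFrame({"effect": [0.0, 1.0, -1.0] * 10,
                             "s2": [2.0] * 30, "df_resid": 10,
                             "n_case": 6, "n_control": 6})
        params, out = moderate(fits)
        assert math.isinf(params.d0)
        assert out.loc[0, "t_mod"] == 0.0

    def test_zero_variance_zero_effect_gives_t_zero(self):
        fits = pd.DataFrame({"effect": [0.0], "s2": [0.0], "df_resid": 4,
                             "n_case": 3, "n_control": 3})
        _, out = moderate(fits, d0=0)
        assert out["t_mod"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0


def test_moderated_t_matches_reference_implementation(tmp_path):
    """Independent cross-check of the whole EB route against limma::eBayes."""
    import os
    import subprocess
    import textwrap

    rng = np.random.default_rng(0)
    n = 300
    sigma2 = 2.0 * 4.0 / rng.chisquare(4.0, n)
    data = np.vstack([rng.normal(0, np.sqrt(s), 12) for s in sigma2])
    data[:20, 6:] += 1.5
    cols = [f"c{i}" for i in range(6)] + [f"t{i}" for i in range(6)]
    expr = pd.DataFrame(data, columns=cols, index=[f"p{i}" for i in range(n)])
    params, out = moderate(fit_two_group(expr, cols[6:], cols[:6]))

    expr.to_csv(tmp_path / "x.csv")
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv(file.path(Sys.getenv('TD'), 'x.csv'),
                                row.names = 1))
        design <- cbind(Intercept = 1, Case = rep(c(0, 1), each = 6))
        fit <- eBayes(lmFit(x, design))
        res <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                          d0 = fit$df.prior, s0 = fit$s2.prior)
        write.csv(res, file.path(Sys.getenv('TD'), 'out.csv'))
    """)
    subprocess.run(["Rscript", "-e", script], check=True,
                   env=dict(os.environ, TD=str(tmp_path)),
                   capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
    assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-10)
    assert params.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-10)
    np.testing.assert_allclose(out["t_mod"], ref["t"], atol=1e-10)
    np.testing.assert_allclose(out["p"], ref["p"], atol=1e-12)


class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
    ])
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_step_up_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        for n in (1, 10, 1000):
            p = rng.uniform(size=n)
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)


class TestCollapse:
    def _de(self):
        return pd.DataFrame({
            "probe_id": ["p1", "p2", "p3", "p4", "p5"],
            "p": [0.001, 0.01, 0.02, 0.01, 0.5],
            "p_adj": [0.2, 0.01, 0.05, 0.05, 0.9],
        })

    def test_keeps_smallest_adjusted_p(self):
        pm = pd.DataFrame({"probe_id": ["p1", "p2"], "transcript_id": ["T1", "T1"]})
        out = collapse_to_transcripts(self._de(), pm)
        assert out["probe_id"].tolist() == ["p2"]

    def test_unmapped_probes_discarded(self):
        pm = pd.DataFrame({"probe_id": ["p1", "p5"],
                           "transcript_id": ["T1", None]})
        out = collapse_to_transcripts(self._de(), pm)
        assert out["probe_id"].tolist() == ["p1"]

    def test_tie_breaks_by_raw_p_then_id(self):
        pm = pd.DataFrame({"probe_id": ["p3", "p4"], "transcript_id": ["T2", "T2"]})
        out = collapse_to_transcripts(self._de(), pm)
        assert out["probe_id"].tolist() == ["p4"]  # same p_adj, smaller raw p


class TestCallDM:
    def _design(self):
        return SampleDesign(pd.DataFrame({
            "sample_id": ["e1", "e2", "o1", "o2"],
            "phenotype": ["EIUM", "EIUM", "OSIS", "OSIS"],
            "treatment": ["control"] * 4}))

    def _call(self, ctrl_mean, case_mean, delta=0.15):
        beta = pd.DataFrame({"e1": [ctrl_mean], "e2": [ctrl_mean],
                             "o1": [case_mean], "o2": [case_mean]},
                            index=["cg1"])
        present = beta.notna()
        return call_dm(beta, present, self._design(), "OSIS", "EIUM", delta=delta)

    def test_above_threshold_called_hyper(self):
        out = self._call(0.50, 0.66)
        assert out["direction"].tolist() == ["hyper"]
        assert out["delta_beta"].iloc[0] == pytest.approx(0.16)

    def test_strict_boundary_not_called(self):
        assert len(self._call(0.50, 0.65)) == 0  # 0.15 is not > 0.15

    def test_hypo_sign(self):
        out = self._call(0.80, 0.55)
        assert out["direction"].tolist() == ["hypo"]
        assert out["delta_beta"].iloc[0] == pytest.approx(-0.25)

    def test_probe_without_present_samples_skipped(self):
        beta = pd.DataFrame({"e1": [0.1], "e2": [0.1], "o1": [0.9], "o2": [0.9]},
                            index=["cg1"])
        present = beta.notna()
        present.loc["cg1", ["o1", "o2"]] = False
        skipped = []
        out = call_dm(beta, present, self._design(), "OSIS", "EIUM",
                      skipped=skipped)
        assert len(out) == 0
        assert skipped == ["cg1"]

    def test_present_only_means(self):
        beta = pd.DataFrame({"e1": [0.2], "e2": [0.9], "o1": [0.6], "o2": [0.6]},
                            index=["cg1"])
        present = beta.notna()
        present.loc["cg1", "e2"] = False  # control mean uses e1 only
        out = call_dm(beta, present, self._design(), "OSIS", "EIUM")
        assert out["delta_beta"].iloc[0] == pytest.approx(0.4)
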