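"""Differential expression (empirical-Bayes moderated t) and differential
methylation (Δβ rule).

The expression side fits an ordinary two-group linear model per probe and
shrinks the residual variances toward a common prior with the classical
moment estimators for the scaled-inverse-chi-square hierarchy: observed
``s² | σ² ~ σ²·χ²_df/df`` with prior ``σ² ~ s0²·d0/χ²_d0``.  The prior
degrees of freedom ``d0`` and prior variance ``s0²`` are recovered from
the empirical mean and variance of ``log s²`` by digamma/trigamma
inversion; the moderated statistic is

    t = effect / (s̃ · sqrt(1/n1 + 1/n2)),   s̃² = (d0·s0² + df·s²)/(d0 + df)

referred to a t distribution with ``d0 + df`` degrees of freedom
(standard normal when ``d0 = ∞``).

The methylation side calls a CpG differentially methylated when the
phenotype-average β-values (present samples only) differ by strictly
more than δ (default 0.15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import SampleDesign

__all__ = [
    "EBParams",
    "fit_two_group",
    "estimate_eb_params",
    "moderate",
    "bh_adjust",
    "de_two_group",
    "collapse_to_transcripts",
    "call_dm",
]


@dataclass(frozen=True)
class EBParams:
    """Empirical-Bayes hyperparameters: prior df (may be inf) and variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def fit_two_group(expr: pd.DataFrame, case_samples, control_samples) -> pd.DataFrame:
    """Per-probe two-group fit: effect (case − control), pooled s², df.

    Equal-variance pooled fit; permutation of samples within a group does
    not change the result.
    """
    case = expr[list(case_samples)].to_numpy(dtype=float)
    ctrl = expr[list(control_samples)].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], case.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    return pd.DataFrame(
        {"effect": effect, "s2": s2, "df_resid": df_resid,
         "n_case": n2, "n_control": n1},
        index=expr.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_eb_params(s2: np.ndarray, df_resid: float,
                       min_probes: int = 10) -> EBParams:
    """Moment-match the marginal of log s² to recover (d0, s0²).

    When the excess dispersion of ``log s²`` over its sampling component
    is non-positive the prior is degenerate: ``d0 = ∞`` and ``s0²`` is the
    common variance.  Probes with non-finite or non-positive ``s²`` are
    ignored during estimation.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < min_probes:
        raise ValueError(
            f"need at least {min_probes} probes with positive variance "
            f"to estimate hyperparameters (got {int(ok.sum())})")
    z = np.log(s2[ok])
    half_df = df_resid / 2.0
    e = z - special.digamma(half_df) + math.log(half_df)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, half_df))
    if excess <= 0:
        return EBParams(d0=math.inf, s0_sq=math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EBParams(d0=d0, s0_sq=s0_sq)


def moderate(fits: pd.DataFrame, params: EBParams | None = None,
             d0: float | None = None) -> tuple[EBParams | None, pd.DataFrame]:
    """Moderated t and p for a table from :func:`fit_two_group`.

    ``d0`` forces the prior degrees of freedom: ``0`` recovers the
    ordinary two-sample t, ``inf`` the z-form with all variances replaced
    by ``s0²``.  Otherwise hyperparameters are estimated (or supplied via
    ``params``).  Probes with zero posterior variance get ``t = 0`` when
    their effect is also zero, ``±inf`` otherwise.
    """
    s2 = fits["s2"].to_numpy(dtype=float)
    effect = fits["effect"].to_numpy(dtype=float)
    df_resid = float(fits["df_resid"].iloc[0])
    n1 = float(fits["n_control"].iloc[0])
    n2 = float(fits["n_case"].iloc[0])
    if d0 == 0:
        params = None  # no shrinkage: ordinary two-sample t
        s2_post = s2
        df_total = df_resid
    else:
        if params is None:
            params = estimate_eb_params(s2, df_resid)
            if d0 is not None:
                if math.isinf(d0):
                    params = EBParams(d0=math.inf, s0_sq=params.s0_sq)
                else:
                    params = EBParams(d0=d0, s0_sq=params.s0_sq)
        if math.isinf(params.d0):
            s2_post = np.full_like(s2, params.s0_sq)
            df_total = math.inf
        else:
            s2_post = (params.d0 * params.s0_sq + df_resid * s2) / (params.d0 + df_resid)
            df_total = params.d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0),
                     np.where(effect == 0, 0.0, np.sign(effect) * np.inf))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fits.copy()
    out["t_mod"] = t
    out["p"] = p
    return params, out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def de_two_group(expr: pd.DataFrame, design: SampleDesign, case: str,
                 control: str, treatment: str | None = None,
                 d0: float | None = None) -> tuple[EBParams, pd.DataFrame]:
    """Full DE contrast: fit, moderate, and BH-adjust.

    ``case``/``control`` name phenotype levels; ``treatment`` optionally
    restricts both groups to one treatment arm.
    """
    case_samples = design.samples(phenotype=case, treatment=treatment)
    control_samples = design.samples(phenotype=control, treatment=treatment)
    fits = fit_two_group(expr, case_samples, control_samples)
    params, table = moderate(fits, d0=d0)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table.insert(0, "probe_id", table.index)
    return params, table.reset_index(drop=True)


def collapse_to_transcripts(de: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """One DE record per transcript: keep the probe with smallest p_adj.

    Probes without a transcript mapping are discarded.  Ties on ``p_adj``
    break by smaller raw ``p``, then lexicographic probe id.
    """
    pm = probe_map.dropna(subset=["transcript_id"])
    pm = pm[pm["transcript_id"].astype(str).str.len() > 0]
    merged = de.merge(pm[["probe_id", "transcript_id"]], on="probe_id", how="inner")
    merged = merged.sort_values(["p_adj", "p", "probe_id"], kind="stable")
    collapsed = merged.drop_duplicates(subset="transcript_id", keep="first")
    cols = ["transcript_id"] + [c for c in collapsed.columns if c != "transcript_id"]
    return collapsed[cols].sort_values("transcript_id").reset_index(drop=True)


def call_dm(
    beta: pd.DataFrame,
    present: pd.DataFrame,
    design: SampleDesign,
    case: str,
    control: str,
    delta: float = 0.15,
    treatment: str | None = None,
    skipped: list | None = None,
) -> pd.DataFrame:
    """Call differentially methylated CpGs by the strict Δβ rule.

    Phenotype means use present samples only.  A record is emitted when
    ``|Δβ| > delta`` strictly (with a 1e-12 float-representation guard so
    a difference that is exactly the threshold is never called);
    ``direction`` is ``hyper`` when the case mean exceeds the control
    mean.  Probes with no present sample in either group are skipped
    (collected into ``skipped`` when a list is supplied).
    """
    case_samples = design.samples(phenotype=case, treatment=treatment)
    ctrl_samples = design.samples(phenotype=control, treatment=treatment)
    masked = beta.where(present.reindex_like(beta))
    mean_case = masked[case_samples].mean(axis=1)
    mean_ctrl = masked[ctrl_samples].mean(axis=1)
    no_data = mean_case.isna() | mean_ctrl.isna()
    if skipped is not None:
        skipped.extend(beta.index[no_data])
    dbeta = mean_case - mean_ctrl
    called = (~no_data) & (dbeta.abs() > delta + 1e-12)
    out = pd.DataFrame({
        "probe_id": beta.index[called],
        "mean_beta_control": mean_ctrl[called].to_numpy(),
        "mean_beta_case": mean_case[called].to_numpy(),
        "delta_beta": dbeta[called].to_numpy(),
    })
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)
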