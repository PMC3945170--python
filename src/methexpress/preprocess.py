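"""Normalization, β-value computation and detection/presence filtering.

Expression intensities get a per-sample variance-stabilizing transform
(log2 with offset by default, arcsinh as alternative) followed by
cross-sample quantile normalization.  Methylation two-color intensities
are quantile-normalized and converted to β = M/(M+U+α).  A probe is
"present" in a sample when its detection p-value is below threshold, and
is retained only when present in enough samples of *each* phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "vst_expression",
    "quantile_normalize",
    "compute_beta",
    "presence_filter",
    "exclude_probes",
    "normalize_chrom",
]


@dataclass
class SampleDesign:
    """Sample sheet: ids plus phenotype and treatment factor levels."""

    frame: pd.DataFrame  # columns: sample_id, phenotype, treatment

    def __post_init__(self) -> None:
        required = {"sample_id", "phenotype", "treatment"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design table")
        counts = self.frame.groupby("phenotype").size()
        if (counts < 2).any():
            raise ValueError("each phenotype needs at least 2 samples")

    @classmethod
    def read_csv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, dtype=str))

    def samples(self, phenotype: str | None = None,
                treatment: str | None = None) -> list[str]:
        f = self.frame
        if phenotype is not None:
            f = f[f["phenotype"] == phenotype]
        if treatment is not None:
            f = f[f["treatment"] == treatment]
        return list(f["sample_id"])

    @property
    def phenotypes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["phenotype"]))


def vst_expression(expr: pd.DataFrame, method: str = "log2_offset",
                   offset: float = 1.0) -> pd.DataFrame:
    """Per-sample monotone variance-stabilizing transform of intensities."""
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("negative intensities are not allowed")
    if method == "log2_offset":
        out = np.log2(values + offset)
    elif method == "arcsinh":
        out = np.arcsinh(values)
    else:
        raise ValueError(f"unknown VST method {method!r}")
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the across-sample mean quantile profile.

    After the transform each column's sorted values equal the mean of the
    per-column sorted vectors; within-column rank order is preserved and
    tied values receive the average of their rank positions' reference
    values.  A single-column matrix is returned unchanged.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("quantile_normalize requires a complete matrix; "
                         "mask missing cells before/after instead")
    n, m = X.shape
    if m < 2 or n == 0:
        return matrix.astype(float).copy()
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    from scipy.stats import rankdata
    for j in range(m):
        ranks = rankdata(X[:, j], method="average")  # 1..n, halves on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_beta(m, u, alpha: float = 100.0):
    """β = M/(M+U+α); array-friendly, result in [0, 1)."""
    m_arr = np.asarray(m, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if (m_arr < 0).any() or (u_arr < 0).any():
        raise ValueError("intensities must be nonnegative")
    beta = m_arr / (m_arr + u_arr + alpha)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if np.isscalar(m) and np.isscalar(u):
        return float(beta)
    return beta


def min_present_for(group_size: int, numerator: int = 5, denominator: int = 6) -> int:
    """Presence quorum scaled from the 5-of-6 rule: ceil(5/6 * group size)."""
    return math.ceil(numerator * group_size / denominator)


def presence_filter(
    detection_p: pd.DataFrame,
    design: SampleDesign,
    p_threshold: float = 0.01,
    min_present: int | None = None,
) -> tuple[pd.Index, pd.DataFrame, pd.DataFrame]:
    """Apply the per-phenotype presence rule.

    A probe is present in a sample iff its detection p-value is below
    ``p_threshold``; it is retained iff it is present in at least
    ``min_present`` samples within *every* phenotype (default: the
    5-of-6 quorum scaled as ``ceil(5/6 * group size)``).

    Returns ``(retained probe index, presence mask, per-group presence
    counts)``.  The mask covers all probes so that downstream group
    means can restrict to present samples.
    """
    groups = {ph: design.samples(phenotype=ph) for ph in design.phenotypes}
    for ph, samples in groups.items():
        missing = set(samples) - set(detection_p.columns)
        if missing:
            raise ValueError(f"samples missing from detection matrix: {sorted(missing)}")
    quorum: dict[str, int] = {}
    for ph, samples in groups.items():
        q = min_present if min_present is not None else min_present_for(len(samples))
        if q > len(samples):
            raise ValueError(
                f"min_present={q} exceeds group size {len(samples)} for {ph!r}")
        quorum[ph] = q
    present = detection_p < p_threshold
    counts = pd.DataFrame(
        {ph: present[samples].sum(axis=1) for ph, samples in groups.items()})
    keep = pd.Series(True, index=detection_p.index)
    for ph, q in quorum.items():
        keep &= counts[ph] >= q
    return detection_p.index[keep], present, counts


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and uppercase (so 'chrX', 'x', 'X' all agree)."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def exclude_probes(records, rules=("sex_chromosomes", "non_cpg")):
    """Drop probes on X/Y and/or non-CpG probes.

    Returns ``(retained records, removal counts per rule)``.  A probe
    failing several rules is counted once, under the first rule hit.
    """
    allowed = {"sex_chromosomes", "non_cpg"}
    bad = set(rules) - allowed
    if bad:
        raise ValueError(f"unknown exclusion rules: {sorted(bad)}")
    retained = []
    removed = {rule: 0 for rule in rules}
    for rec in records:
        rule_hit = None
        if "sex_chromosomes" in rules and normalize_chrom(rec.chrom) in ("X", "Y"):
            rule_hit = "sex_chromosomes"
        elif "non_cpg" in rules and not rec.is_cpg:
            rule_hit = "non_cpg"
        if rule_hit is None:
            retained.append(rec)
        else:
            removed[rule_hit] += 1
    return retained, removed
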