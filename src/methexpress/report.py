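"""Dataset-level summaries exported as plot-ready tables.

PCA variance fractions and sample coordinates, an agglomerative sample
tree, per-sample β-value densities and hyper/hypo differential
methylation counts — numbers only, no figure rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PCASummary",
    "ClusterTree",
    "pca_summary",
    "hclust",
    "beta_density",
    "dm_scatter_counts",
    "dm_heatmap_table",
]


@dataclass
class PCASummary:
    variance_fraction: np.ndarray
    coordinates: pd.DataFrame  # samples × (PC1, PC2)


@dataclass
class ClusterTree:
    linkage: np.ndarray  # scipy linkage matrix (merge pairs + heights)
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def pca_summary(matrix: pd.DataFrame, n_components: int = 2) -> PCASummary:
    """PCA of samples on feature-centered data (covariance scaling).

    ``matrix`` is features × samples.  Variance fractions are the
    eigenvalue shares of the sample covariance; a constant matrix yields
    all-zero fractions.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    centered = X - X.mean(axis=1, keepdims=True)
    # SVD of samples-in-rows view; singular-value squares share = variance share
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    total = float((s ** 2).sum())
    fractions = (s ** 2) / total if total > 0 else np.zeros_like(s)
    k = min(n_components, s.size)
    coords = U[:, :k] * s[:k]
    coordinates = pd.DataFrame(
        coords, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)])
    return PCASummary(variance_fraction=fractions, coordinates=coordinates)


def hclust(matrix: pd.DataFrame, metric: str = "euclidean",
           linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of samples (columns).

    Returns the merge sequence with heights and the dendrogram leaf
    order; ties follow the deterministic ordering of the underlying
    nearest-neighbour chain, so identical input gives identical trees.
    """
    X = matrix.to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    order = [matrix.columns[i] for i in hierarchy.leaves_list(Z)]
    return ClusterTree(linkage=Z, leaf_order=order)


def beta_density(beta: pd.DataFrame, bandwidth: float = 0.03,
                 step: float = 0.005) -> pd.DataFrame:
    """Per-sample Gaussian-kernel density of β on a fixed [0, 1] grid.

    Boundary mass is folded back by reflection at 0 and 1 so each
    sample's density integrates to ≈ 1 over the grid.  Returns a frame
    with a ``beta`` grid column and one column per sample.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(0.0, 1.0 + step / 2, step)
    out = {"beta": grid}
    for sample in beta.columns:
        x = beta[sample].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if ((x < 0) | (x > 1)).any():
            raise ValueError("β-values must lie in [0, 1]")
        diffs = (grid[:, None] - x[None, :]) / bandwidth
        refl_lo = (grid[:, None] + x[None, :]) / bandwidth
        refl_hi = (grid[:, None] - (2.0 - x[None, :])) / bandwidth
        kernel = (np.exp(-0.5 * diffs ** 2) + np.exp(-0.5 * refl_lo ** 2)
                  + np.exp(-0.5 * refl_hi ** 2))
        out[sample] = kernel.sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    return pd.DataFrame(out)


def dm_scatter_counts(dm: pd.DataFrame) -> dict:
    """Hyper/hypo counts of DM calls (the scatter-plot corner numbers)."""
    n_hyper = int((dm["direction"] == "hyper").sum()) if len(dm) else 0
    n_hypo = int((dm["direction"] == "hypo").sum()) if len(dm) else 0
    total = n_hyper + n_hypo
    return {
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "n_total": total,
        "hyper_fraction": n_hyper / total if total else float("nan"),
    }


def dm_heatmap_table(dm: pd.DataFrame, beta: pd.DataFrame, samples: list[str],
                     records=None) -> pd.DataFrame:
    """Per-CpG β rows ordered by Δβ with context columns (heat-map export)."""
    ordered = dm.sort_values("delta_beta", kind="stable")
    table = beta.loc[ordered["probe_id"], samples].copy()
    table.insert(0, "delta_beta", ordered["delta_beta"].to_numpy())
    if records is not None:
        ctx = {r.probe_id: r.island_context for r in records}
        table.insert(1, "island_context",
                     [ctx.get(p, "") for p in ordered["probe_id"]])
    table.index.name = "probe_id"
    return table
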