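"""k-means over training methylation profiles and gap-statistic selection of k.

The training samples are clustered on all M methylation outcomes with
Lloyd's algorithm (k-means++ seeding, multiple restarts).  The number of
clusters is chosen with the gap statistic: the log within-cluster
dispersion of the data is compared with its mean under B reference
datasets drawn uniformly over each feature's observed range, and the
smallest k whose gap is within one simulation standard error of the next
gap ("firstSEmax") is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["ClusterModel", "GapCurve", "fit_kmeans", "gap_statistic", "assign_by_centroid"]

DEFAULT_N_INIT = 10
DEFAULT_K_GRID = tuple(range(2, 16))


@dataclass
class ClusterModel:
    """A fitted k-means model; labels are 1-based (1..k)."""

    k: int
    centroids: np.ndarray        # k x M
    train_labels: np.ndarray     # 1..k
    within_dispersion: float     # W_k, within-cluster sum of squares
    seed: int
    n_init: int

    def __post_init__(self):
        labels = np.unique(self.train_labels)
        if labels.min() < 1 or labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if labels.size < self.k:
            raise ValueError("every cluster must be nonempty")


@dataclass
class GapCurve:
    k_grid: tuple
    gap: np.ndarray
    se: np.ndarray
    chosen_k: int
    n_reference: int
    log_w: np.ndarray = field(default=None)

    def __post_init__(self):
        if len(self.gap) != len(self.k_grid):
            raise ValueError("gap and k_grid lengths differ")
        if self.chosen_k not in self.k_grid:
            raise ValueError("chosen_k must lie on the grid")


def fit_kmeans(
    train_outcomes: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
) -> ClusterModel:
    """Best-of-``n_init`` Lloyd's k-means (k-means++ seeding)."""
    x = np.asarray(train_outcomes, dtype=float)
    if np.isnan(x).any():
        raise ValueError("training outcomes contain missing values")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of training samples {x.shape[0]}")
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=seed,
        tol=1e-4, max_iter=300,
    ).fit(x)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        train_labels=km.labels_ + 1,
        within_dispersion=float(km.inertia_),
        seed=seed,
        n_init=n_init,
    )


def _log_w(x, k, seed, n_init):
    if k == 1:
        centered = x - x.mean(axis=0)
        w = float(np.sum(centered * centered))
    else:
        w = fit_kmeans(x, k, seed=seed, n_init=n_init).within_dispersion
    if w <= 0.0:
        raise ValueError(
            f"zero within-cluster dispersion at k={k}; reduce the k grid"
        )
    return np.log(w)


def gap_statistic(
    train_outcomes: np.ndarray,
    k_grid=DEFAULT_K_GRID,
    n_reference: int = 50,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
    selection: str = "firstSEmax",
) -> GapCurve:
    """Gap statistic over ``k_grid`` with a uniform-box reference.

    Gap(k) = mean_b log W*_kb - log W_k; the standard error carries the
    sqrt(1 + 1/B) factor.  Selection is "firstSEmax" (smallest k with
    Gap(k) >= Gap(k+1) - se(k+1)) or "global_max".
    """
    x = np.asarray(train_outcomes, dtype=float)
    k_grid = tuple(int(k) for k in k_grid)
    if min(k_grid) < 1 or max(k_grid) > x.shape[0]:
        raise ValueError("k_grid must lie within [1, n_train]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo, hi = x.min(axis=0), x.max(axis=0)

    log_w = np.array([_log_w(x, k, seed, n_init) for k in k_grid])
    log_w_ref = np.empty((n_reference, len(k_grid)))
    for b in range(n_reference):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_seed = int(rng.integers(2**31 - 1))
        log_w_ref[b] = [_log_w(ref, k, ref_seed, n_init) for k in k_grid]

    gap = log_w_ref.mean(axis=0) - log_w
    sd = log_w_ref.std(axis=0, ddof=0)
    se = sd * np.sqrt(1.0 + 1.0 / n_reference)

    if selection == "global_max":
        chosen = k_grid[int(np.argmax(gap))]
    elif selection == "firstSEmax":
        chosen = k_grid[-1]
        for i in range(len(k_grid) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                chosen = k_grid[i]
                break
    else:
        raise ValueError(f"unknown selection rule {selection!r}")
    return GapCurve(
        k_grid=k_grid, gap=gap, se=se, chosen_k=chosen,
        n_reference=n_reference, log_w=log_w,
    )


def assign_by_centroid(model: ClusterModel, new_outcomes: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) labels for new samples; ties take the
    lowest label.  Diagnostic only — the main pipeline assigns test
    clusters through CMMP, not centroids."""
    x = np.asarray(new_outcomes, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match centroids "
            f"({model.centroids.shape[1]})"
        )
    d2 = (
        np.sum(x * x, axis=1)[:, None]
        - 2.0 * x @ model.centroids.T
        + np.sum(model.centroids**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1) + 1
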