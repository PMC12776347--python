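"""Metrics and simulation experiment grids.

Implements the simulation study's measurements: MSE of each predictor
against the true mixed effect (optionally restricted to racial-minority
samples), adjusted Rand index between estimated and true clusterings in
the training and test sets, cluster-covariate association tests, and the
one-parameter-at-a-time experiment grids comparing the naive estimate,
regression prediction, k-means + CMMP, and oracle CMMP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .clustering import fit_kmeans
from .mixed_model import ClusterDesign, build_design, ols_fit
from .predict import predict_all
from .simulate import SimulatedDataset, SimulationConfig, generate_dataset

__all__ = [
    "mse_vs_truth",
    "adjusted_rand_index",
    "cluster_covariate_tests",
    "ExperimentGrid",
    "replicate_metrics",
    "run_grid",
    "grid_boxplot",
]

GRID_VALUES = {
    "b": (0.5, 0.6, 0.681, 0.78, 0.9),
    "c": (1, 2, 4, 6, 8, 10, 16),
    "sigma": (0.1, 0.2, 0.5, 1.0, 2.0),
    "k": (1, 2, 4, 6, 8, 10, 16, 20),
}
PARAM_FIELDS = {"b": "bias", "c": "n_clusters", "sigma": "sigma_alpha"}


def mse_vs_truth(theta_hat: np.ndarray, theta: np.ndarray, subset=None) -> float:
    """Mean over (subset samples x outcomes) of (theta_hat - theta)^2."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if theta_hat.shape != theta.shape:
        raise ValueError("prediction and truth shapes differ")
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        if not subset.any():
            raise ValueError("empty evaluation subset")
        theta_hat, theta = theta_hat[subset], theta[subset]
    return float(np.mean((theta_hat - theta) ** 2))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Pair-counting ARI with expected-index correction (<= 1)."""
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.size != labels_b.size:
        raise ValueError("label vectors have different lengths")
    if labels_a.size < 2:
        raise ValueError("need at least two samples")
    return float(adjusted_rand_score(labels_a, labels_b))


def cluster_covariate_tests(labels, covariates: pd.DataFrame) -> pd.DataFrame:
    """Association of cluster labels with each covariate.

    One-way ANOVA F for numeric covariates, Pearson chi-squared for
    categoricals, Bonferroni-adjusted over the covariates tested
    (capped at 1).  Constant covariates are flagged with NA p-values.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        if col.nunique() < 2:
            rows.append((name, "constant", np.nan, np.nan))
            continue
        if pd.api.types.is_numeric_dtype(col):
            groups = [col.to_numpy()[labels == g] for g in np.unique(labels)]
            stat, p = stats.f_oneway(*groups)
            kind = "anova_f"
        else:
            table = pd.crosstab(labels, col)
            stat, p, _, _ = stats.chi2_contingency(table)
            kind = "chi2"
        rows.append((name, kind, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p_value"])
    n_tested = int(out["p_value"].notna().sum())
    out["p_adjusted"] = np.minimum(out["p_value"] * max(n_tested, 1), 1.0)
    return out


@dataclass
class ExperimentGrid:
    """A one-parameter sweep: vary one of {b, c, sigma, k} over ``values``
    holding the base configuration fixed."""

    vary: str
    values: tuple
    base_config: SimulationConfig = field(default_factory=SimulationConfig)
    n_replicates: int = 30
    k_fit: int = 6                 # clusters passed to k-means (unless vary == "k")

    def __post_init__(self):
        if self.vary not in GRID_VALUES:
            raise ValueError(f"vary must be one of {tuple(GRID_VALUES)}")
        self.values = tuple(self.values)


def _dataset_arrays(ds: SimulatedDataset):
    tr, te = ds.train_mask, ds.test_mask
    design = build_design(ds.covariates.loc[tr])
    x_tr = design.X
    x_te = design.transform(ds.covariates.loc[te])
    return tr, te, x_tr, x_te


def replicate_metrics(
    config: SimulationConfig,
    seed: int,
    k_values=(6,),
    methods=("naive", "regression", "cmmp", "oracle"),
    kmeans_n_init: int = 10,
) -> pd.DataFrame:
    """Run one simulated replicate end to end and score every method.

    Returns a tidy frame with one row per (method, k): overall and
    minority-restricted MSE against the true mixed effect, and train/test
    ARI for the CMMP methods (test assignment is the per-sample consensus
    over outcomes).
    """
    ds = generate_dataset(config, seed)
    tr, te, x_tr, x_te = _dataset_arrays(ds)
    y_tr, y_te = ds.y[tr], ds.y[te]
    theta_te = ds.theta[te]
    true_tr, true_te = ds.clusters[tr], ds.clusters[te]
    minority_te = ds.minority_mask[te]

    rows = []

    def add(method, k, pred, ari_train=np.nan):
        ari_test = np.nan
        if pred.consensus is not None:
            ari_test = adjusted_rand_index(pred.consensus, true_te)
        rows.append(
            {
                "method": method,
                "k": k,
                "mse": mse_vs_truth(pred.theta_hat, theta_te),
                "mse_minority": mse_vs_truth(pred.theta_hat, theta_te, minority_te),
                "ari_train": ari_train,
                "ari_test": ari_test,
            }
        )

    if "naive" in methods:
        add("naive", np.nan, predict_all(y_te, x_te, mode="naive"))
    if "regression" in methods:
        betas, _ = ols_fit(y_tr, x_tr)
        add("regression", np.nan,
            predict_all(y_te, x_te, mode="regression", ols_betas=betas))
    if "oracle" in methods:
        cd = ClusterDesign(x_tr, true_tr)
        fits = [cd.fit(y_tr[:, j]) for j in range(y_tr.shape[1])]
        add("oracle", np.nan, predict_all(y_te, x_te, fits=fits, mode="oracle"),
            ari_train=adjusted_rand_index(true_tr, true_tr))
    if "cmmp" in methods:
        for k in k_values:
            model = fit_kmeans(y_tr, k, seed=seed, n_init=kmeans_n_init)
            cd = ClusterDesign(x_tr, model.train_labels)
            fits = [cd.fit(y_tr[:, j]) for j in range(y_tr.shape[1])]
            add("cmmp", k, predict_all(y_te, x_te, fits=fits, mode="cmmp"),
                ari_train=adjusted_rand_index(model.train_labels, true_tr))
    return pd.DataFrame(rows)


def run_grid(grid: ExperimentGrid, seed: int = 0) -> pd.DataFrame:
    """Execute a one-parameter sweep; tidy long-format results.

    Each (value, replicate) cell generates a fresh dataset, clusters the
    training outcomes, fits the per-outcome mixed models, predicts under
    all four methods, and records MSE, minority MSE, and train/test ARI.
    Replicate seeds are derived from ``seed`` by a counter scheme, so a
    cell's draws do not depend on the other cells.
    """
    frames = []
    for vi, value in enumerate(grid.values):
        if grid.vary == "k":
            config = grid.base_config
            k_values = (int(value),)
        else:
            config = replace(grid.base_config, **{PARAM_FIELDS[grid.vary]: value})
            k_values = (grid.k_fit,)
        for rep in range(grid.n_replicates):
            rep_seed = int(
                np.random.SeedSequence(seed, spawn_key=(vi, rep)).generate_state(1)[0]
                % (2**31 - 1)
            )
            out = replicate_metrics(config, rep_seed, k_values=k_values)
            out.insert(0, "replicate", rep)
            out.insert(0, "value", value)
            out.insert(0, "parameter", grid.vary)
            frames.append(out)
    return pd.concat(frames, ignore_index=True)


def grid_boxplot(results: pd.DataFrame, metric: str = "mse", path=None):
    """Boxplots of a grid metric by parameter value and method (optional
    PNG output; matplotlib imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = sorted(results["value"].unique())
    methods = [m for m in ("naive", "oracle", "cmmp", "regression")
               if m in set(results["method"])]
    fig, ax = plt.subplots(figsize=(1.8 * len(values) + 2, 4))
    width = 0.8 / max(len(methods), 1)
    for mi, method in enumerate(methods):
        data = [
            results.query("method == @method and value == @v")[metric].to_numpy()
            for v in values
        ]
        pos = [i + (mi - (len(methods) - 1) / 2) * width for i in range(len(values))]
        ax.boxplot(data, positions=pos, widths=width * 0.9,
                   label=method, patch_artist=True)
    ax.set_xticks(range(len(values)), [str(v) for v in values])
    ax.set_xlabel(results["parameter"].iloc[0])
    ax.set_ylabel(metric)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
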