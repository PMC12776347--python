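"""End-to-end pipeline: split, cluster, fit, predict, bootstrap, evaluate.

Drives the whole method on either a synthetic dataset (full latent truth
available, so oracle CMMP and true-MSE evaluation run too) or
user-supplied matrices.  Writes all artifacts as CSV/JSON/YAML plus a
manifest (parameters, seeds, file hashes) sufficient for an exact rerun.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .bootstrap import bootstrap_mse
from .clustering import fit_kmeans, gap_statistic
from .evaluation import adjusted_rand_index, mse_vs_truth
from .io import child_seed, file_sha256
from .mixed_model import ClusterDesign, build_design, ols_fit
from .predict import predict_all
from .simulate import SimulationConfig, generate_dataset, write_dataset

__all__ = ["RunConfig", "run_pipeline"]

# seed-stream stage indices (counter-based: adding a stage never shifts others)
STAGE_SIMULATE, STAGE_KMEANS, STAGE_GAP, STAGE_BOOTSTRAP = 0, 1, 2, 3


@dataclass
class RunConfig:
    out_dir: str = "methmix_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    k: int | None = None              # fixed k; None -> gap-statistic selection
    k_grid: tuple = tuple(range(2, 16))
    gap_references: int = 50
    modes: tuple = ("naive", "regression", "cmmp", "oracle")
    bootstrap_B: int = 0              # 0 disables the bootstrap stage
    bootstrap_variant: str = "as_written"


def run_pipeline(config: RunConfig) -> pathlib.Path:
    """Execute the full synthetic-mode pipeline and write artifacts."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_seed = child_seed(config.seed, STAGE_SIMULATE)
    ds = generate_dataset(config.simulation, sim_seed)
    write_dataset(ds, out / "dataset")

    tr, te = ds.train_mask, ds.test_mask
    if not te.any():
        raise ValueError("empty test set")
    design = build_design(ds.covariates.loc[tr])
    x_tr = design.X
    x_te = design.transform(ds.covariates.loc[te])
    y_tr, y_te = ds.y[tr], ds.y[te]

    if config.k is None:
        gap = gap_statistic(
            y_tr, config.k_grid, n_reference=config.gap_references,
            seed=child_seed(config.seed, STAGE_GAP),
        )
        k = gap.chosen_k
        pd.DataFrame(
            {"k": gap.k_grid, "gap": gap.gap, "se": gap.se}
        ).to_csv(out / "gap_curve.csv", index=False)
    else:
        k = config.k
    model = fit_kmeans(y_tr, k, seed=child_seed(config.seed, STAGE_KMEANS))
    pd.DataFrame(model.centroids).to_csv(out / "centroids.csv")
    with open(out / "cluster_model.json", "w") as fh:
        json.dump(
            {"k": model.k, "seed": model.seed, "n_init": model.n_init,
             "within_dispersion": model.within_dispersion,
             "train_labels": model.train_labels.tolist()},
            fh,
        )

    cd = ClusterDesign(x_tr, model.train_labels)
    fits = [cd.fit(y_tr[:, j]) for j in range(y_tr.shape[1])]
    _write_fits(fits, out / "fits.csv", design.columns)

    test_ids = ds.covariates.index[te]
    outcome_ids = [f"m{j + 1:04d}" for j in range(y_tr.shape[1])]
    long_rows = []
    preds = {}
    metrics = []
    for mode in config.modes:
        if mode == "oracle":
            cd_or = ClusterDesign(x_tr, ds.clusters[tr])
            fits_or = [cd_or.fit(y_tr[:, j]) for j in range(y_tr.shape[1])]
            pred = predict_all(y_te, x_te, fits=fits_or, mode="oracle")
        elif mode == "cmmp":
            pred = predict_all(y_te, x_te, fits=fits, mode="cmmp")
        elif mode == "regression":
            betas, _ = ols_fit(y_tr, x_tr)
            pred = predict_all(y_te, x_te, mode="regression", ols_betas=betas)
        else:
            pred = predict_all(y_te, x_te, mode="naive")
        preds[mode] = pred
        for ni, sid in enumerate(test_ids):
            for mi, oid in enumerate(outcome_ids):
                long_rows.append(
                    (sid, oid, mode,
                     int(pred.assigned[ni, mi]) if pred.assigned is not None else "",
                     pred.theta_hat[ni, mi])
                )
        row = {"method": mode, "mse": mse_vs_truth(pred.theta_hat, ds.theta[te])}
        if pred.consensus is not None:
            row["ari_test"] = adjusted_rand_index(pred.consensus, ds.clusters[te])
        metrics.append(row)
    pd.DataFrame(
        long_rows, columns=["sample", "outcome", "method", "assigned_cluster", "theta_hat"]
    ).to_csv(out / "predictions.csv", index=False)
    pd.DataFrame(metrics).to_csv(out / "metrics.csv", index=False)

    if config.bootstrap_B > 0 and "cmmp" in preds:
        pred = preds["cmmp"]
        result = bootstrap_mse(
            fits, pred.assigned, x_tr, model.train_labels, x_te,
            B=config.bootstrap_B,
            seed=child_seed(config.seed, STAGE_BOOTSTRAP),
            variant=config.bootstrap_variant,
            theta_hat=pred.theta_hat,
        )
        boot = pd.DataFrame(result.mse, index=test_ids, columns=outcome_ids)
        boot.to_csv(out / "bootstrap_mse.csv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "k": int(k),
        "config": {k_: v for k_, v in asdict(config).items() if k_ != "simulation"},
        "simulation": asdict(config.simulation),
        "files": {
            p.name: file_sha256(p) for p in sorted(out.glob("*.csv"))
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return out


def read_fits(path) -> tuple[list, list]:
    """Read per-outcome fits written by the pipeline back into
    :class:`~methmix.mixed_model.OutcomeFit` objects.

    Returns (fits, design column names) with columns recovered from the
    ``beta[...]`` headers.
    """
    from .mixed_model import OutcomeFit

    table = pd.read_csv(path)
    beta_cols = [c for c in table.columns if c.startswith("beta[")]
    alpha_cols = sorted(
        (c for c in table.columns if c.startswith("alpha_")),
        key=lambda c: int(c.split("_")[1]),
    )
    design_columns = [c[5:-1] for c in beta_cols]
    fits = []
    for _, row in table.iterrows():
        g, r = float(row["G_hat"]), float(row["R_hat"])
        fits.append(
            OutcomeFit(
                beta_hat=row[beta_cols].to_numpy(dtype=float),
                G_hat=g,
                R_hat=r,
                alpha_hat=row[alpha_cols].to_numpy(dtype=float),
                converged=bool(row["converged"]),
                loglik=float(row["loglik"]),
                gamma=g / r,
                n_clusters=len(alpha_cols),
            )
        )
    return fits, design_columns


def _write_fits(fits, path, design_columns):
    rows = []
    for j, f in enumerate(fits):
        row = {"outcome": f"m{j + 1:04d}", "G_hat": f.G_hat, "R_hat": f.R_hat,
               "converged": f.converged, "loglik": f.loglik}
        for name, val in zip(design_columns, f.beta_hat):
            row[f"beta[{name}]"] = val
        for g, a in enumerate(f.alpha_hat, start=1):
            row[f"alpha_{g}"] = a
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
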