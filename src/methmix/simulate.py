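"""Synthetic pan-cancer methylation data with cluster random intercepts.

Generates datasets with the statistical structure of a two-cancer
(CESC + LUAD) Infinium-450K-style cohort after M-value transformation and
within-cancer standardization: per-sample covariates (CNA levels, race,
age, sex, stage, cancer type), latent cluster memberships, and methylation
outcomes

    y_im = x_i' beta_m + alpha_{j_i, m} + eps_im = theta_im + eps_im

where ``theta`` is the denoised mixed effect that downstream predictors
target.  The random intercepts of designated outcome blocks share a common
positive covariance ("clumpy dependence"); all other pairs are independent.

A controllable bias parameter ``b`` fixes the proportion of White samples
exactly, emulating the under-representation of racial minorities in public
genomic cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "sample_covariates",
    "sample_random_intercepts",
    "generate_dataset",
    "empirical_snr",
    "write_dataset",
]

RACE_LEVELS = ("AI/AN", "Asian", "Black", "NHPI", "White")
STAGE_LEVELS = ("I", "II", "III", "IV")
CANCER_LEVELS = ("CESC", "LUAD")
CNA_LEVELS = (-2, -1, 0, 1, 2)


def _default_nonwhite() -> dict:
    return {"Black": 0.55, "Asian": 0.35, "AI/AN": 0.06, "NHPI": 0.04}


def _default_stage() -> dict:
    return {"I": 0.45, "II": 0.20, "III": 0.25, "IV": 0.10}


def _default_cna() -> dict:
    return {-2: 0.005, -1: 0.03, 0: 0.93, 1: 0.03, 2: 0.005}


@dataclass
class SimulationConfig:
    """Data-generating parameters for the synthetic cohort.

    Defaults reflect the reference configuration: n=655 samples, M=2275
    outcomes, 65 CNA covariates, White fraction b=.78, c=6 latent clusters,
    random-intercept SD sigma=.2, error variance .9, fixed-effect
    coefficient variance .03, and two outcome blocks of M/4 outcomes each
    with within-block intercept covariance .07.
    """

    n_samples: int = 655
    n_outcomes: int = 2275
    n_cna: int = 65
    bias: float = 0.78               # proportion of samples assigned race White
    n_clusters: int = 6
    sigma_alpha: float = 0.2         # SD of the cluster random intercept
    error_variance: float = 0.9
    beta_variance: float = 0.03
    block_covariance: float = 0.07   # within-block intercept covariance
    n_blocks: int = 2
    block_size: int | None = None    # default n_outcomes // 4
    block_cov_mode: str = "covariance"   # or "correlation"
    strict_psd: bool = False
    train_fraction_cesc: float = 0.7
    stratify_split: bool = True      # stratify the CESC split by race
    seed: int = 0
    # covariate stand-in distributions (config-overridable)
    p_cesc: float = 254.0 / 655.0
    p_female_luad: float = 0.45
    race_nonwhite: dict = field(default_factory=_default_nonwhite)
    stage_probs: dict = field(default_factory=_default_stage)
    cna_probs: dict = field(default_factory=_default_cna)
    age_mean: float = 60.0
    age_sd: float = 13.0
    age_range: tuple = (20.0, 90.0)

    def __post_init__(self):
        if not 0.0 < self.bias < 1.0:
            raise ValueError(f"bias b must lie in (0, 1), got {self.bias}")
        if self.error_variance <= 0:
            raise ValueError("error_variance must be positive")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be nonnegative")
        if self.bias < 1.0 and not self.race_nonwhite:
            raise ValueError("non-White race distribution is empty while b < 1")
        for name, table in (("race_nonwhite", self.race_nonwhite),
                            ("stage_probs", self.stage_probs),
                            ("cna_probs", self.cna_probs)):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if self.block_size is None:
            self.block_size = self.n_outcomes // 4
        if self.block_size * self.n_blocks > self.n_outcomes:
            raise ValueError("blocks exceed the number of outcomes")

    @property
    def effective_block_covariance(self) -> float:
        """Within-block intercept covariance actually used for sampling.

        The nominal covariance combined with a small marginal variance
        sigma^2 can be non-PSD (covariance > variance).  In ``covariance``
        mode the value is clamped to .99*sigma^2 with a warning (or an
        error under ``strict_psd``); in ``correlation`` mode the nominal
        value is read as a correlation and scaled by sigma^2.
        """
        s2 = self.sigma_alpha ** 2
        if self.block_cov_mode == "correlation":
            return self.block_covariance * s2
        if self.block_cov_mode != "covariance":
            raise ValueError(f"unknown block_cov_mode {self.block_cov_mode!r}")
        if self.block_covariance <= s2:
            return self.block_covariance
        if self.strict_psd:
            raise ValueError(
                f"block covariance {self.block_covariance} exceeds intercept "
                f"variance sigma^2={s2}: requested structure is not PSD"
            )
        warnings.warn(
            f"block covariance {self.block_covariance} > sigma^2={s2}; "
            f"clamping to 0.99*sigma^2",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.99 * s2

    def block_slices(self) -> list[slice]:
        """Outcome-index slices of the dependence blocks (deterministic:
        the blocks occupy the first n_blocks*block_size outcome indices)."""
        return [slice(b * self.block_size, (b + 1) * self.block_size)
                for b in range(self.n_blocks)]


@dataclass
class SimulatedDataset:
    """A generated cohort with full latent truth."""

    covariates: pd.DataFrame        # n_samples rows
    y: np.ndarray                   # observed outcomes, n x M
    theta: np.ndarray               # true mixed effects, n x M
    clusters: np.ndarray            # true cluster labels, 1..c
    betas: np.ndarray               # true coefficients, p x M (truth design)
    alphas: np.ndarray              # true intercepts, c x M
    train_mask: np.ndarray          # boolean, n
    test_mask: np.ndarray           # boolean, n
    design_columns: list            # columns of the truth design
    config: SimulationConfig

    def __post_init__(self):
        if np.any(self.train_mask & self.test_mask) or not np.all(
            self.train_mask | self.test_mask
        ):
            raise ValueError("train/test masks must be disjoint and exhaustive")

    @property
    def minority_mask(self) -> np.ndarray:
        return (self.covariates["race"] != "White").to_numpy()


def sample_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-sample covariate table.

    Exactly ``round(b * n)`` samples (round-half-even) are assigned race
    White; the rest are drawn from the renormalized non-White distribution.
    Sex is sampled conditionally on cancer type, with CESC always female.
    """
    n = config.n_samples
    n_white = int(round(config.bias * n))

    race = np.empty(n, dtype=object)
    white_rows = rng.permutation(n)[:n_white]
    race[:] = ""
    race[white_rows] = "White"
    nonwhite_rows = np.flatnonzero(race == "")
    levels = list(config.race_nonwhite)
    probs = np.array([config.race_nonwhite[r] for r in levels], dtype=float)
    race[nonwhite_rows] = rng.choice(levels, size=nonwhite_rows.size, p=probs)

    cancer = np.where(rng.random(n) < config.p_cesc, "CESC", "LUAD")
    sex = np.where(
        cancer == "CESC",
        "female",
        np.where(rng.random(n) < config.p_female_luad, "female", "male"),
    )

    stage_levels = list(config.stage_probs)
    stage = rng.choice(
        stage_levels, size=n,
        p=np.array([config.stage_probs[s] for s in stage_levels], dtype=float),
    )

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b_ = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b_, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    cna_levels = np.array(list(config.cna_probs), dtype=float)
    cna_p = np.array([config.cna_probs[k] for k in config.cna_probs], dtype=float)
    cna = rng.choice(cna_levels, size=(n, config.n_cna), p=cna_p)

    table = pd.DataFrame(
        {
            "race": race,
            "age": age,
            "sex": sex,
            "stage": stage,
            "cancer_type": cancer,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id"),
    )
    for j in range(config.n_cna):
        table[f"cna_{j + 1:03d}"] = cna[:, j]
    return table


def sample_random_intercepts(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw the c x M cluster random-intercept matrix.

    Each cluster's M-vector is an independent zero-mean Gaussian with
    marginal variance sigma^2, within-block covariance equal to the
    effective block covariance, and zero covariance off-block.  Sampling
    uses the exchangeable-block factorization (one shared factor per block
    plus an idiosyncratic term), never a dense M x M Cholesky.
    """
    c, m = config.n_clusters, config.n_outcomes
    s2 = config.sigma_alpha ** 2
    if s2 == 0.0:
        return np.zeros((c, m))
    tau = config.effective_block_covariance
    alpha = rng.normal(0.0, config.sigma_alpha, size=(c, m))
    if tau > 0.0:
        for sl in config.block_slices():
            width = sl.stop - sl.start
            shared = rng.normal(0.0, np.sqrt(tau), size=(c, 1))
            idio = rng.normal(0.0, np.sqrt(s2 - tau), size=(c, width))
            alpha[:, sl] = shared + idio
    return alpha


def _split_masks(
    covariates: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """All LUAD samples train; a seeded fraction of CESC samples train.

    When ``stratify_split`` is on, the CESC hold-out is drawn within each
    race level (levels with a single CESC sample stay in training), which
    keeps every observed race level represented in the training set.
    """
    n = len(covariates)
    is_cesc = (covariates["cancer_type"] == "CESC").to_numpy()
    test = np.zeros(n, dtype=bool)
    test_frac = 1.0 - config.train_fraction_cesc
    if test_frac <= 0.0:
        raise ValueError("train_fraction_cesc leaves an empty test set")

    if config.stratify_split:
        race = covariates["race"].to_numpy()
        for level in np.unique(race[is_cesc]):
            rows = np.flatnonzero(is_cesc & (race == level))
            n_test = int(round(test_frac * rows.size))
            n_test = min(n_test, rows.size - 1)
            if n_test > 0:
                test[rng.permutation(rows)[:n_test]] = True
    else:
        rows = np.flatnonzero(is_cesc)
        n_test = int(round(test_frac * rows.size))
        test[rng.permutation(rows)[:n_test]] = True

    if not test.any():
        raise ValueError("empty test set; increase n or reduce train fraction")
    return ~test, test


def generate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate one complete cohort: covariates, truth, and observed outcomes.

    Per outcome m the coefficient vector beta_m is N(0, beta_variance * I)
    on the truth design (intercept, CNA, standardized age, and
    reference-coded categoricals), cluster labels are uniform on 1..c,
    intercepts come from :func:`sample_random_intercepts`, and errors are
    independent N(0, error_variance).  Identical config+seed reproduces
    the dataset bit for bit.
    """
    from .mixed_model import build_design  # local import to avoid a cycle

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    covariates = sample_covariates(config, rng)
    design = build_design(
        covariates, age_center=config.age_mean, age_scale=config.age_sd
    )
    x = design.X
    p = x.shape[1]
    m = config.n_outcomes

    betas = rng.normal(0.0, np.sqrt(config.beta_variance), size=(p, m))
    clusters = rng.integers(1, config.n_clusters + 1, size=config.n_samples)
    alphas = sample_random_intercepts(config, rng)
    theta = x @ betas + alphas[clusters - 1]
    eps = rng.normal(0.0, np.sqrt(config.error_variance), size=theta.shape)
    y = theta + eps
    train_mask, test_mask = _split_masks(covariates, config, rng)

    return SimulatedDataset(
        covariates=covariates,
        y=y,
        theta=theta,
        clusters=clusters,
        betas=betas,
        alphas=alphas,
        train_mask=train_mask,
        test_mask=test_mask,
        design_columns=list(design.columns),
        config=replace(config, seed=seed),
    )


def empirical_snr(X: np.ndarray, beta_hat: np.ndarray, error_variance: float) -> float:
    """Signal-to-noise ratio Var(X beta_hat) / sigma_hat^2.

    ``beta_hat`` may be a single p-vector or a p x M matrix (the mean SNR
    across outcomes is returned).
    """
    if error_variance <= 0:
        raise ValueError("estimated error variance must be positive")
    beta_hat = np.atleast_2d(np.asarray(beta_hat, dtype=float))
    if beta_hat.shape[0] != X.shape[1]:
        beta_hat = beta_hat.T
    linpred = X @ beta_hat
    return float(np.mean(np.var(linpred, axis=0, ddof=1)) / error_variance)


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write a dataset to a directory of CSV/YAML files (samples as rows)."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = dataset.covariates.index
    cols = [f"m{j + 1:04d}" for j in range(dataset.y.shape[1])]
    dataset.covariates.to_csv(outdir / "covariates.csv")
    pd.DataFrame(dataset.y, index=ids, columns=cols).to_csv(outdir / "outcomes.csv")
    pd.DataFrame(dataset.theta, index=ids, columns=cols).to_csv(outdir / "truth_theta.csv")
    pd.DataFrame(
        {
            "cluster": dataset.clusters,
            "train": dataset.train_mask.astype(int),
            "test": dataset.test_mask.astype(int),
        },
        index=ids,
    ).to_csv(outdir / "truth_clusters.csv")
    cfg = dataset.config
    meta = {
        "n_samples": cfg.n_samples,
        "n_outcomes": cfg.n_outcomes,
        "n_cna": cfg.n_cna,
        "bias": cfg.bias,
        "n_clusters": cfg.n_clusters,
        "sigma_alpha": cfg.sigma_alpha,
        "error_variance": cfg.error_variance,
        "beta_variance": cfg.beta_variance,
        "block_covariance": cfg.block_covariance,
        "seed": cfg.seed,
    }
    with open(outdir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
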