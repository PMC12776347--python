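"""Feature preparation for Infinium-450K-style methylation and CNA tables.

Fixed pipeline order: boundary beta values (exact 0/1) marked missing →
features with any missing cell or not shared between the two cohorts
dropped → methylation SD filter (reference cohort only) → CNA variance
filter (top 15%) → CNA correlation pruning (pairwise |r| <= .7) →
M-value transform → within-cancer-type standardization.  Every dropped
feature is accounted for exactly once in the :class:`FeatureFilterReport`.

All matrices are pandas DataFrames with samples as rows and features as
columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureFilterReport",
    "mark_boundary_missing",
    "drop_missing_or_unshared",
    "filter_methyl_by_sd",
    "filter_cna",
    "m_value_transform",
    "standardize_within_group",
    "greedy_correlation_prune",
    "run_preprocess",
]


@dataclass
class FeatureFilterReport:
    n_input_methyl: int = 0
    n_input_cna: int = 0
    dropped_missing: list = field(default_factory=list)
    dropped_unshared: list = field(default_factory=list)
    dropped_low_sd: list = field(default_factory=list)
    dropped_low_variance_cna: list = field(default_factory=list)
    dropped_correlated_cna: list = field(default_factory=list)
    n_output_methyl: int = 0
    n_output_cna: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def mark_boundary_missing(beta_matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace exact 0 and exact 1 beta values with missing.

    Strict equality only: values like 1 - 1e-9 are retained.  Values
    outside [0, 1] raise.
    """
    vals = beta_matrix.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta values must lie in [0, 1]")
    out = beta_matrix.astype(float).mask((beta_matrix == 0.0) | (beta_matrix == 1.0))
    return out


def drop_missing_or_unshared(a: pd.DataFrame, b: pd.DataFrame):
    """Keep features present in both cohorts with no missing cell in either.

    Returns the two filtered matrices (feature order taken from ``a``)
    and a report listing unshared and missing-dropped features.
    """
    shared = [c for c in a.columns if c in set(b.columns)]
    if not shared:
        raise ValueError("the two matrices share no features")
    unshared = sorted(set(a.columns).symmetric_difference(b.columns))
    complete = [
        c for c in shared
        if not (a[c].isna().any() or b[c].isna().any())
    ]
    if not complete:
        raise ValueError("no shared feature is complete in both cohorts")
    dropped_missing = [c for c in shared if c not in set(complete)]
    report = FeatureFilterReport(
        n_input_methyl=len(set(a.columns) | set(b.columns)),
        dropped_unshared=unshared,
        dropped_missing=dropped_missing,
        n_output_methyl=len(complete),
    )
    return a[complete], b[complete], report


def filter_methyl_by_sd(
    m: pd.DataFrame, threshold: float = 0.2, reference_samples=None
) -> pd.DataFrame:
    """Keep features whose sample SD (ddof=1) over the reference samples
    is at least ``threshold`` (closed at the threshold)."""
    ref = m if reference_samples is None else m.loc[list(reference_samples)]
    if len(ref) < 2:
        raise ValueError("SD undefined with fewer than two reference samples")
    sd = ref.std(axis=0, ddof=1)
    return m.loc[:, sd >= threshold]


def greedy_correlation_prune(corr: pd.DataFrame, threshold: float) -> list:
    """Features retained after iteratively removing the feature with the
    most above-threshold partners (ties: larger mean absolute correlation,
    then later input position removed).  Deterministic; near-maximal
    retention."""
    names = list(corr.columns)
    c = np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(c, 0.0)
    adj = c > threshold
    alive = np.ones(len(names), dtype=bool)
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        cand = np.flatnonzero(deg == deg.max())
        if cand.size > 1:
            mean_abs = np.where(alive, c, 0.0).sum(axis=1)[cand]
            cand = cand[mean_abs == mean_abs.max()]
        alive[cand[-1]] = False
    return [n for n, a in zip(names, alive) if a]


def filter_cna(
    cna: pd.DataFrame,
    variance_quantile: float = 0.85,
    corr_threshold: float = 0.7,
    reference_samples=None,
    signed: bool = False,
):
    """Two-stage CNA covariate filter.

    Stage 1 keeps features with variance at or above the empirical
    ``variance_quantile`` (linear-interpolation) of feature variances;
    stage 2 prunes correlated pairs (absolute correlation by default)
    with :func:`greedy_correlation_prune`.
    """
    ref = cna if reference_samples is None else cna.loc[list(reference_samples)]
    if len(ref) < 2:
        raise ValueError("need at least two reference samples")
    variances = ref.var(axis=0, ddof=1)
    if np.allclose(variances, 0.0):
        raise ValueError("all CNA features are constant")
    cut = float(np.quantile(variances.to_numpy(), variance_quantile))
    stage1 = variances.index[variances >= cut].tolist()
    dropped_var = [c for c in cna.columns if c not in set(stage1)]

    corr = ref[stage1].corr()
    if signed:
        corr = corr.clip(lower=0.0)
    keep = greedy_correlation_prune(corr, corr_threshold)
    dropped_corr = [c for c in stage1 if c not in set(keep)]

    report = FeatureFilterReport(
        n_input_cna=cna.shape[1],
        dropped_low_variance_cna=dropped_var,
        dropped_correlated_cna=dropped_corr,
        n_output_cna=len(keep),
    )
    return cna[keep], report


def m_value_transform(beta_matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise M-value transform y = log2(x / (1 - x)).

    Values must lie strictly in (0, 1); boundary values reaching this
    stage indicate a pipeline-ordering violation.  Missing propagates.
    """
    vals = beta_matrix.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
        raise ValueError(
            "M-value transform needs values strictly inside (0, 1); "
            "mark boundary values missing first"
        )
    return pd.DataFrame(
        np.log2(vals / (1.0 - vals)),
        index=beta_matrix.index,
        columns=beta_matrix.columns,
    )


def standardize_within_group(m: pd.DataFrame, group) -> pd.DataFrame:
    """Per feature, per group: subtract the group mean and divide by the
    group sample SD (ddof=1)."""
    group = pd.Series(np.asarray(group), index=m.index)
    counts = group.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"groups with fewer than two samples: {small}")
    out = m.astype(float).copy()
    for g, block in out.groupby(group, sort=False):
        sd = block.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = sd.index[sd == 0][0]
            raise ValueError(f"feature {bad!r} is constant within group {g!r}")
        out.loc[block.index] = (block - block.mean(axis=0)) / sd
    return out


def run_preprocess(
    methyl_a: pd.DataFrame,
    methyl_b: pd.DataFrame,
    cna_a: pd.DataFrame,
    cna_b: pd.DataFrame,
    sd_threshold: float = 0.2,
    variance_quantile: float = 0.85,
    corr_threshold: float = 0.7,
):
    """Full preprocessing of a two-cohort dataset.

    Cohort ``a`` is the reference used for all filters (the cohort of
    primary interest); group labels for standardization are the cohort of
    origin.  Returns (methylation M-values standardized within cohort,
    CNA covariates, combined FeatureFilterReport).
    """
    ma = mark_boundary_missing(methyl_a)
    mb = mark_boundary_missing(methyl_b)
    ma, mb, rep_m = drop_missing_or_unshared(ma, mb)
    kept = filter_methyl_by_sd(ma, sd_threshold).columns
    rep_m.dropped_low_sd = [c for c in ma.columns if c not in set(kept)]
    ma, mb = ma[kept], mb[kept]
    rep_m.n_output_methyl = len(kept)

    ca, cb, rep_c = drop_missing_or_unshared(cna_a, cna_b)
    n_cna_in = rep_c.n_input_methyl
    ca_f, rep_c2 = filter_cna(
        ca, variance_quantile=variance_quantile, corr_threshold=corr_threshold
    )
    cb_f = cb[ca_f.columns]

    report = FeatureFilterReport(
        n_input_methyl=rep_m.n_input_methyl,
        n_input_cna=n_cna_in,
        dropped_missing=rep_m.dropped_missing + rep_c.dropped_missing,
        dropped_unshared=rep_m.dropped_unshared + rep_c.dropped_unshared,
        dropped_low_sd=rep_m.dropped_low_sd,
        dropped_low_variance_cna=rep_c2.dropped_low_variance_cna,
        dropped_correlated_cna=rep_c2.dropped_correlated_cna,
        n_output_methyl=rep_m.n_output_methyl,
        n_output_cna=rep_c2.n_output_cna,
    )

    methyl = pd.concat([ma, mb])
    groups = np.array(["a"] * len(ma) + ["b"] * len(mb))
    mvals = m_value_transform(methyl)
    standardized = standardize_within_group(mvals, groups)
    cna = pd.concat([ca_f, cb_f])
    return standardized, cna, report
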