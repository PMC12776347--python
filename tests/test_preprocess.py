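import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmix.preprocess import (
    drop_missing_or_unshared,
    filter_cna,
    filter_methyl_by_sd,
    greedy_correlation_prune,
    m_value_transform,
    mark_boundary_missing,
    run_preprocess,
    standardize_within_group,
)


def frame(data, columns=None):
    return pd.DataFrame(data, columns=columns, dtype=float)


class TestBoundaryMissing:
    def test_exact_boundaries_become_missing(self):
        out = mark_boundary_missing(frame([[0.0, 0.5, 1.0]], columns=list("abc")))
        assert out.isna().to_numpy().tolist() == [[True, False, True]]
        assert out.iloc[0, 1] == 0.5

    def test_near_boundary_retained(self):
        out = mark_boundary_missing(frame([[1.0 - 1e-9, 1e-9]]))
        assert not out.isna().any().any()

    def test_interior_matrix_unchanged(self):
        m = frame([[0.2, 0.8], [0.4, 0.6]])
        pd.testing.assert_frame_equal(mark_boundary_missing(m), m)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mark_boundary_missing(frame([[1.2]]))


class TestSharedComplete:
    def test_intersection_order_preserved(self):
        a = frame([[0.1, 0.2, 0.3]], columns=["p", "q", "r"])
        b = frame([[0.1, 0.2, 0.3]], columns=["q", "r", "s"])
        fa, fb, rep = drop_missing_or_unshared(a, b)
        assert list(fa.columns) == ["q", "r"] == list(fb.columns)
        assert sorted(rep.dropped_unshared) == ["p", "s"]

    def test_missing_cell_in_either_drops_feature(self):
        a = frame([[0.1, 0.2]], columns=["q", "r"])
        b = frame([[np.nan, 0.3]], columns=["q", "r"])
        fa, _, rep = drop_missing_or_unshared(a, b)
        assert list(fa.columns) == ["r"]
        assert rep.dropped_missing == ["q"]

    def test_identity_on_identical_complete(self):
        a = frame([[0.1, 0.2], [0.3, 0.4]], columns=["q", "r"])
        fa, fb, rep = drop_missing_or_unshared(a, a.copy())
        pd.testing.assert_frame_equal(fa, a)
        assert rep.n_output_methyl == 2

    def test_empty_intersection_raises(self):
        a = frame([[0.1]], columns=["p"])
        b = frame([[0.1]], columns=["q"])
        with pytest.raises(ValueError):
            drop_missing_or_unshared(a, b)


class TestSDFilter:
    def test_hand_computed_threshold(self):
        # sample SDs: feature f1 ~ .1936 (< .2), f2 ~ .2160 (>= .2)
        m = frame(
            {"f1": [0.3, 0.5, 0.5, 0.7], "f2": [0.3, 0.5, 0.5, 0.82]}
        )
        sd = m.std(ddof=1)
        assert sd["f1"] < 0.2 < sd["f2"]
        out = filter_methyl_by_sd(m, 0.2)
        assert list(out.columns) == ["f2"]

    def test_constant_feature_dropped(self):
        m = frame({"f": [0.4, 0.4, 0.4]})
        assert filter_methyl_by_sd(m).shape[1] == 0

    def test_alternating_unit_values_kept(self):
        m = pd.DataFrame({"f": [-1.0, 1.0, -1.0, 1.0]})
        assert list(filter_methyl_by_sd(m).columns) == ["f"]

    def test_single_reference_sample_rejected(self):
        with pytest.raises(ValueError):
            filter_methyl_by_sd(frame({"f": [0.4]}))


def brute_force_max_independent_set(corr, threshold):
    """Largest subset with all pairwise |r| <= threshold, by enumeration."""
    names = list(corr.columns)
    c = np.abs(corr.to_numpy())
    best = []
    for r in range(len(names), 0, -1):
        for subset in itertools.combinations(range(len(names)), r):
            if all(c[i, j] <= threshold for i, j in itertools.combinations(subset, 2)):
                return [names[i] for i in subset]
    return best


class TestCNAFilter:
    def test_perfectly_correlated_pair_pruned(self, rng):
        base = rng.normal(size=50)
        cna = pd.DataFrame({"g1": base, "g2": 2.0 * base, "g3": rng.normal(size=50)})
        kept, rep = filter_cna(cna, variance_quantile=0.0)
        assert len(kept.columns) == 2
        assert len(rep.dropped_correlated_cna) == 1
        assert "g3" in kept.columns

    def test_uncorrelated_features_untouched(self, rng):
        cna = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("wxyz"))
        kept, rep = filter_cna(cna, variance_quantile=0.0)
        assert list(kept.columns) == list("wxyz")

    def test_path_graph_retains_maximum_independent_set(self):
        # correlation graph forming a path g1-g2-g3-g4-g5 at rho=.9:
        # only adjacent pairs exceed the .7 threshold
        names = [f"g{i}" for i in range(1, 6)]
        c = np.eye(5)
        for i in range(4):
            c[i, i + 1] = c[i + 1, i] = 0.9
        corr = pd.DataFrame(c, index=names, columns=names)
        kept = greedy_correlation_prune(corr, 0.7)
        brute = brute_force_max_independent_set(corr, 0.7)
        assert len(brute) == 3
        assert len(kept) == len(brute)

    def test_all_constant_rejected(self):
        cna = pd.DataFrame({"g1": [1.0, 1.0], "g2": [2.0, 2.0]})
        with pytest.raises(ValueError):
            filter_cna(cna)

    def test_variance_quantile_top_15_percent(self, rng):
        cna = pd.DataFrame(
            rng.normal(size=(200, 20)) * np.arange(1, 21)[None, :],
            columns=[f"g{i}" for i in range(20)],
        )
        kept, rep = filter_cna(cna, variance_quantile=0.85, corr_threshold=1.1)
        assert kept.shape[1] == 3  # 15% of 20 features


class TestMValue:
    @pytest.mark.parametrize("x,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_reference_points(self, x, expected):
        out = m_value_transform(frame([[x]]))
        assert out.iloc[0, 0] == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1 - 1e-6), min_size=2, max_size=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_strictly_increasing(self, values):
        out = m_value_transform(frame([values])).to_numpy().ravel()
        order = np.argsort(values)
        diffs = np.diff(out[order])
        assert np.all(diffs[np.diff(np.sort(values)) > 0] > 0)

    def test_antisymmetry(self):
        x = frame([[0.3, 0.7]])
        out = m_value_transform(x).to_numpy().ravel()
        assert out[0] == pytest.approx(-out[1])

    def test_boundary_values_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            m_value_transform(frame([[0.0, 0.5]]))


class TestStandardize:
    def test_hand_computed_two_groups(self):
        m = frame({"f": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0]})
        groups = ["a", "a", "a", "b", "b", "b"]
        out = standardize_within_group(m, groups)
        expected = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        assert np.allclose(out["f"], expected)

    def test_single_group_is_zscore(self, rng):
        m = pd.DataFrame({"f": rng.normal(3.0, 2.0, size=30)})
        out = standardize_within_group(m, ["g"] * 30)
        assert out["f"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["f"].std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        groups = ["g1"] * 20 + ["g2"] * 20
        once = standardize_within_group(m, groups)
        twice = standardize_within_group(once, groups)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)

    def test_zero_sd_names_feature_and_group(self):
        m = frame({"f": [1.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'f'.*'a'"):
            standardize_within_group(m, ["a", "a", "b", "b"])


def test_full_pipeline_report_accounts_for_every_feature(rng):
    n = 30
    beta_a = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(n, 6)),
        columns=[f"cg{i}" for i in range(6)],
    )
    beta_a["cg0"] = rng.uniform(0.45, 0.55, size=n)        # low SD, dropped
    beta_a.loc[0, "cg1"] = 0.0                             # boundary -> missing
    beta_b = beta_a.copy() + rng.uniform(-0.01, 0.01, size=beta_a.shape)
    beta_b = beta_b.clip(0.05, 0.95)
    beta_b = beta_b.drop(columns=["cg2"])                  # unshared
    base = rng.normal(size=n)
    cna_a = pd.DataFrame(
        {"g1": base, "g2": base + rng.normal(0, 0.1, n), "g3": rng.normal(size=n)}
    )
    cna_b = cna_a + rng.normal(0, 0.05, size=cna_a.shape)
    mvals, cna, rep = run_preprocess(
        beta_a, beta_b, cna_a, cna_b, variance_quantile=0.0
    )
    dropped_m = len(rep.dropped_missing) + len(rep.dropped_unshared) + len(rep.dropped_low_sd)
    assert rep.n_output_methyl == rep.n_input_methyl - dropped_m
    assert rep.n_output_cna == rep.n_input_cna - len(rep.dropped_low_variance_cna) - len(
        rep.dropped_correlated_cna
    )
    assert mvals.shape[1] == rep.n_output_methyl
    assert cna.shape[1] == rep.n_output_cna
    # standardized within each cohort
    assert np.allclose(mvals.iloc[:n].mean(), 0.0, atol=1e-10)
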