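"""Spearman inference, exact permutation p-values, thresholding, Fisher z.

The exact p-value path is checked against an independent brute-force
enumeration oracle (Pearson correlation of ranks over every permutation of
one vector), written here and never shared with the implementation.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cfosnet import (
    UndefinedCorrelationError,
    all_pairs_z,
    correlation_matrix,
    fisher_z,
    spearman_pair,
    threshold_network,
)

# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------


def brute_force_spearman(x, y):
    """(rho, two-sided exact p) by enumerating all permutations of y.

    Pearson correlation of the rank vectors, evaluated for every one of the
    n! rearrangements of y's ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    perms = np.array(list(itertools.permutations(ry)))
    pc = perms - perms.mean(axis=1, keepdims=True)
    rxc = rx - rx.mean()
    rhos = (pc @ rxc) / np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
    return rho_obs, float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


class TestSpearmanPair:
    def test_monotone_identity(self):
        rho, p, n = spearman_pair([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == 1.0
        assert n == 5

    def test_reversal(self):
        rho, _, _ = spearman_pair([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == -1.0

    def test_exact_p_concordant_n5(self):
        # 2 of the 120 rank assignments attain |rho| = 1
        _, p, _ = spearman_pair([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], method="exact")
        assert p == pytest.approx(2 / 120)

    def test_missing_pairs_dropped(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 6, np.nan, 10, 12]
        rho, _, n = spearman_pair(x, y)
        assert n == 4
        assert rho == 1.0

    def test_constant_input_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_pair([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match=">= 3"):
            spearman_pair([1, 2], [3, 4])

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_enumeration_oracle(self, n, rng):
        for _ in range(25):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p, _ = spearman_pair(x, y, method="exact")
            rho_ref, p_ref = brute_force_spearman(x, y)
            assert rho == pytest.approx(rho_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_p_with_ties_matches_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=6).astype(float)  # heavy ties
            y = rng.integers(0, 4, size=6).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p, _ = spearman_pair(x, y, method="exact")
            rho_ref, p_ref = brute_force_spearman(x, y)
            assert rho == pytest.approx(rho_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_t_approximation_agrees_with_reference(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p, _ = spearman_pair(x, y, method="t_approx")
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_auto_selects_exact_at_study_scale(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        _, p_auto, _ = spearman_pair(x, y, method="auto")
        _, p_exact, _ = spearman_pair(x, y, method="exact")
        assert p_auto == p_exact

    @given(
        data=st.lists(
            # well-separated values so affine/exp maps stay strictly monotone
            # in floating point (no collapse into ties)
            st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
            min_size=5, max_size=9, unique_by=(lambda t: t[0], lambda t: t[1]),
        ),
        shift=st.floats(0.1, 10),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, data, shift):
        x = np.array([t[0] for t in data], dtype=float) / 10.0
        y = np.array([t[1] for t in data], dtype=float) / 10.0
        rho, p, _ = spearman_pair(x, y)
        # exp and affine maps are strictly increasing
        rho2, p2, _ = spearman_pair(np.exp(x / 50.0), shift * y + 3.0)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)


class TestFisherZ:
    @pytest.mark.parametrize(
        "rho, expected",
        [(0.0, 0.0), (0.5, 0.5 * math.log(3)), (-0.5, -0.5 * math.log(3)),
         (0.9, math.atanh(0.9))],
    )
    def test_closed_form(self, rho, expected):
        assert fisher_z(rho) == pytest.approx(expected, abs=1e-9)

    def test_exact_one_clamped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(-1.0) == -fisher_z(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(max_examples=100, derandomize=True)
    def test_odd_and_strictly_increasing(self, a, b):
        assert fisher_z(-a) == pytest.approx(-fisher_z(a), abs=1e-12)
        if a < b:
            assert fisher_z(a) < fisher_z(b)


class TestCorrelationMatrix:
    def test_all_435_pairs_defined(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        assert corr.n_defined_pairs() == 435
        assert np.allclose(corr.rho, corr.rho.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(corr.rho)))

    def test_duplicate_region_gives_rho_one(self, cohort_factory, rng):
        X = rng.lognormal(5, 0.4, size=(8, 30))
        X[:, 1] = X[:, 0]
        corr = correlation_matrix(cohort_factory(X))
        assert corr.rho[0, 1] == 1.0

    def test_iid_noise_large_n_has_no_strong_pairs(self, cohort_factory, rng):
        # null sd of rho ~ 1/sqrt(n-1) ~ 0.032 at n=1000
        X = rng.normal(size=(1000, 30))
        corr = correlation_matrix(cohort_factory(np.abs(X)))
        iu = np.triu_indices(30, 1)
        assert np.nanmax(np.abs(corr.rho[iu])) < 0.2

    def test_constant_region_recorded_undefined_not_zero(self, cohort_factory, rng):
        X = rng.lognormal(5, 0.4, size=(8, 30))
        X[:, 3] = 7.0
        corr = correlation_matrix(cohort_factory(X))
        assert np.all(np.isnan(corr.rho[3, :]))
        assert corr.n_defined_pairs() == 435 - 29

    def test_pairwise_complete_sample_sizes(self, cohort_factory, rng):
        X = rng.lognormal(5, 0.4, size=(8, 30))
        X[0, 0] = np.nan
        X[1, 2] = np.nan
        corr = correlation_matrix(cohort_factory(X))
        assert corr.n_pairs[0, 2] == 6  # two different animals dropped
        assert corr.n_pairs[0, 5] == 7
        assert corr.n_pairs[4, 5] == 8

    def test_missing_and_complete_paths_agree(self, cohort_factory, rng):
        # a NaN far away must not change an unaffected pair's rho/p
        X = rng.lognormal(5, 0.4, size=(8, 30))
        corr_full = correlation_matrix(cohort_factory(X))
        X2 = X.copy()
        X2[0, 29] = np.nan
        corr_miss = correlation_matrix(cohort_factory(X2))
        assert corr_miss.rho[0, 1] == pytest.approx(corr_full.rho[0, 1], abs=1e-12)
        assert corr_miss.pvals[0, 1] == pytest.approx(corr_full.pvals[0, 1], abs=1e-12)

    def test_too_few_animals_rejected(self, cohort_factory, rng):
        with pytest.raises(ValueError, match=">= 3"):
            correlation_matrix(cohort_factory(rng.lognormal(5, 0.4, size=(2, 30))))


class TestThresholdNetwork:
    def test_nothing_passes_at_p_half(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        corr.pvals[:] = 0.5
        net = threshold_network(corr, alpha=0.05)
        assert net.n_edges == 0
        assert np.all(net.z_weights == 0)

    def test_positive_edge_weight_is_atanh_rho(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        i, j = 0, 1
        corr.rho[i, j] = corr.rho[j, i] = 0.9
        corr.pvals[i, j] = corr.pvals[j, i] = 0.01
        net = threshold_network(corr, alpha=0.05)
        assert net.z_weights[i, j] == pytest.approx(math.atanh(0.9))

    def test_negative_edge_kept_but_unweighted(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        corr.pvals[:] = 0.5
        corr.pvals[2, 3] = corr.pvals[3, 2] = 0.01
        corr.rho[2, 3] = corr.rho[3, 2] = -0.9
        net = threshold_network(corr, alpha=0.05)
        assert net.n_edges == 1
        assert net.edges[0].sign == -1
        assert net.z_weights[2, 3] == 0.0

    def test_strict_inequality_at_threshold(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        corr.pvals[:] = 0.5
        corr.pvals[0, 1] = corr.pvals[1, 0] = 0.05  # exactly alpha: excluded
        net = threshold_network(corr, alpha=0.05)
        assert net.n_edges == 0

    def test_invalid_alpha_rejected(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        for alpha in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError, match="alpha"):
                threshold_network(corr, alpha=alpha)

    def test_edge_sets_nest_in_alpha(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        alphas = [0.001, 0.01, 0.05, 0.2, 0.5, 0.999]
        nets = [threshold_network(corr, alpha=a) for a in alphas]
        for small, large in zip(nets, nets[1:]):
            assert small.edge_set() <= large.edge_set()
        # alpha -> 1 approaches the complete signed network; only pairs whose
        # exact p saturates at 1 (observed |rho| near 0) can stay out
        iu = np.triu_indices(30, 1)
        assert nets[-1].n_edges == int((corr.pvals[iu] < 0.999).sum())
        assert nets[-1].n_edges > 400
        assert threshold_network(corr, alpha=1e-9).n_edges == 0

    def test_fdr_flag_is_more_conservative(self, cohort_factory, rng):
        X = rng.lognormal(5, 0.4, size=(8, 30))
        corr = correlation_matrix(cohort_factory(X))
        plain = threshold_network(corr, alpha=0.05)
        adjusted = threshold_network(corr, alpha=0.05, fdr=True)
        assert adjusted.edge_set() <= plain.edge_set()


class TestAllPairsZ:
    def test_length_and_order(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        z = all_pairs_z(corr)
        assert z.shape == (435,)
        iu = np.triu_indices(30, 1)
        assert z[0] == pytest.approx(np.arctanh(corr.rho[iu][0]))

    def test_zero_matrix_gives_zero_vector(self, random_cohort):
        corr = correlation_matrix(random_cohort)
        corr.rho[~np.isnan(corr.rho)] = 0.0
        assert np.all(all_pairs_z(corr) == 0.0)

    def test_two_conditions_support_t868(self, cohort_factory, rng):
        za = all_pairs_z(correlation_matrix(cohort_factory(rng.lognormal(5, 0.4, (8, 30)))))
        zb = all_pairs_z(correlation_matrix(cohort_factory(rng.lognormal(5, 0.4, (8, 30)))))
        assert za.size + zb.size - 2 == 868
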