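"""Substitution models: rate matrices, transition probabilities, accounting."""

import numpy as np
import pytest

from mitopart.models import (DegenerateModelError, ModelError,
                             PartitionedModel, SubstitutionModel,
                             build_rate_matrix, count_free_parameters,
                             discrete_gamma_rates, map_to_available,
                             n_free_parameters, transition_probabilities,
                             uniform_partitioned_model)
from mitopart.partitions import CharSet, PartitionScheme


def random_gtr(rng) -> SubstitutionModel:
    return SubstitutionModel("GTR", tuple(rng.random(6) + 0.1),
                             tuple(rng.dirichlet([5] * 4)))


class TestRateMatrix:
    def test_jc_off_diagonals_are_one_third(self):
        Q = build_rate_matrix(SubstitutionModel.jc())
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)

    def test_detailed_balance_for_random_gtr(self, rng):
        for _ in range(10):
            m = random_gtr(rng)
            Q = m.rate_matrix
            pi = np.array(m.base_freqs)
            flux = pi[:, None] * Q
            assert np.abs(flux - flux.T).max() < 1e-12

    def test_normalization_by_independent_arithmetic(self, rng):
        m = random_gtr(rng)
        ex, pi = np.array(m.exchangeabilities), np.array(m.base_freqs)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        # expected total rate = sum_i pi_i sum_{j!=i} r_ij pi_j, recomputed
        # without the matrix code path
        mu = sum(pi[i] * ex[k] * pi[j] + pi[j] * ex[k] * pi[i]
                 for k, (i, j) in enumerate(pairs))
        Q = m.rate_matrix
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0, abs=1e-12)
        # and the normalization constant itself is mu
        Qraw = np.zeros((4, 4))
        for k, (i, j) in enumerate(pairs):
            Qraw[i, j] = ex[k] * pi[j]
            Qraw[j, i] = ex[k] * pi[i]
        np.fill_diagonal(Qraw, -Qraw.sum(axis=1))
        assert np.allclose(Qraw / mu, Q)

    def test_rows_sum_to_zero(self, rng):
        Q = random_gtr(rng).rate_matrix
        assert np.abs(Q.sum(axis=1)).max() < 1e-12


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, rng):
        P = transition_probabilities(random_gtr(rng).with_gamma(0.5), 0.0)
        for Pc in P:
            assert np.allclose(Pc, np.eye(4), atol=1e-12)

    def test_long_time_reaches_stationarity(self, rng):
        m = random_gtr(rng)
        P = transition_probabilities(m, 100.0)
        for Pc in P:
            assert np.abs(Pc - np.array(m.base_freqs)).max() < 1e-8

    def test_jc_closed_form(self):
        t = 0.37
        P = transition_probabilities(SubstitutionModel.jc(), t)[0]
        same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        expect = np.full((4, 4), diff)
        np.fill_diagonal(expect, same)
        assert np.allclose(P, expect, atol=1e-12)

    @pytest.mark.parametrize("t", [0.0, 1e-3, 0.1, 1.0, 10.0, 100.0])
    def test_rows_sum_to_one(self, rng, t):
        m = random_gtr(rng).with_gamma(0.7)
        P = transition_probabilities(m, t)
        assert np.abs(P.sum(axis=2) - 1.0).max() < 1e-10

    def test_negative_time_rejected(self):
        with pytest.raises(ModelError):
            transition_probabilities(SubstitutionModel.jc(), -0.1)


class TestGammaCategories:
    def test_category_rates_average_to_one(self):
        for shape in (0.2, 0.8, 2.0, 50.0):
            r = discrete_gamma_rates(shape, 4)
            assert r.mean() == pytest.approx(1.0)
            assert (np.diff(r) > 0).all()

    def test_large_shape_collapses_to_uniform_rates(self):
        r = discrete_gamma_rates(1e4, 4)
        assert np.abs(r - 1).max() < 0.05


class TestFamilies:
    @pytest.mark.parametrize("family,expected", [
        ("TVM", "GTR"), ("TIM1", "GTR"), ("TIM2", "GTR"), ("TIM3", "GTR"),
        ("TPM3", "GTR"), ("TrN", "GTR"),
        ("GTR", "GTR"), ("HKY", "HKY"), ("JC", "JC"), ("SYM", "SYM"),
    ])
    def test_substitution_rule(self, family, expected):
        assert map_to_available(family) == expected

    def test_unknown_family_rejected(self):
        with pytest.raises(ModelError):
            map_to_available("BANANA")

    @pytest.mark.parametrize("family,k", [
        ("JC", 0), ("K80", 1), ("HKY", 4), ("TrN", 5), ("TPM", 5),
        ("TIM", 6), ("TVM", 7), ("SYM", 5), ("GTR", 8),
    ])
    def test_free_parameter_table(self, family, k):
        assert n_free_parameters(family, gamma=False) == k
        assert n_free_parameters(family, gamma=True) == k + 1

    def test_mapped_family_never_less_parameterized(self):
        for fam in ("TVM", "TIM", "TPM", "TrN", "HKY", "GTR", "JC"):
            mapped = map_to_available(fam)
            assert (n_free_parameters(mapped, True)
                    >= n_free_parameters(fam if fam in
                                         ("HKY", "GTR", "JC") else fam, True))

    def test_family_constraint_enforced(self):
        with pytest.raises(ModelError, match="tied"):
            SubstitutionModel("K80", (1, 2, 1, 1, 3, 1), (0.25,) * 4)

    def test_degenerate_frequency_detected(self):
        with pytest.raises((DegenerateModelError, ModelError)):
            build_rate_matrix(SubstitutionModel("GTR", (1,) * 6,
                                                (0.5, 0.5, 0.0, 0.0)))


def _scheme(sizes):
    charsets, off = [], 0
    for i, s in enumerate(sizes):
        charsets.append(CharSet(f"c{i}", tuple(range(off, off + s))))
        off += s
    return PartitionScheme("test", charsets, off)


class TestFreeParameterSums:
    @pytest.mark.parametrize("k,expected", [
        (1, 9), (4, 39), (13, 129), (37, 369), (63, 629),
    ])
    def test_gtr_g_sums_match_printed_table_arithmetic(self, k, expected):
        scheme = _scheme([10] * k)
        pm = uniform_partitioned_model(scheme, "GTR", gamma_shape=1.0)
        assert count_free_parameters(scheme, pm) == expected

    def test_multiplier_weighted_mean_must_be_one(self):
        with pytest.raises(ModelError, match="mean"):
            PartitionedModel([SubstitutionModel.jc()] * 2,
                             np.array([2.0, 2.0]), np.array([5.0, 5.0]))
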