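"""MCMC machinery: diagnostics, estimators, proposals, determinism."""

import numpy as np
import pytest

from mitopart.mcmc import (ChainState, McmcConfig, McmcError, Priors,
                           assess_stationarity, effective_sample_size,
                           harmonic_mean_lnL, propose, run_mcmc)
from mitopart.models import SubstitutionModel
from mitopart.partitions import CharSet, PartitionScheme, single_partition
from mitopart.seqdata import Alignment
from mitopart.trees import Tree, topology_key


class TestEffectiveSampleSize:
    def test_iid_series_ess_near_n(self):
        rng = np.random.default_rng(7)
        n = 10_000
        ess = effective_sample_size(rng.standard_normal(n)).value
        assert abs(ess - n) / n < 0.10

    def test_ar1_ess_matches_closed_form(self):
        # ESS/n -> (1-rho)/(1+rho) = 1/3 at rho = 0.5
        rng = np.random.default_rng(11)
        n, rho = 30_000, 0.5
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        ess = effective_sample_size(x).value
        assert abs(ess - n / 3) / (n / 3) < 0.15

    def test_constant_series_flagged_degenerate(self):
        res = effective_sample_size(np.ones(100))
        assert res.value == 0.0
        assert res.degenerate

    def test_too_short_series_rejected(self):
        with pytest.raises(McmcError):
            effective_sample_size(np.arange(5))


class TestHarmonicMean:
    def test_constant_samples_return_that_value(self):
        assert harmonic_mean_lnL([-12.5] * 40) == pytest.approx(-12.5)

    def test_hand_arithmetic_two_samples(self):
        # lnL = {0, 1}: HM of {1, e} = 2 / (1 + e^-1)
        expect = np.log(2.0 / (1.0 + np.exp(-1.0)))
        assert harmonic_mean_lnL([0.0, 1.0]) == pytest.approx(expect,
                                                              abs=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(-50, 3, size=200)
        k = -299_950.0
        assert harmonic_mean_lnL(x + k) == pytest.approx(
            harmonic_mean_lnL(x) + k, abs=1e-6)

    def test_stable_at_mitogenome_scale(self):
        x = np.full(100, -3.0e5) + np.linspace(0, 5, 100)
        assert np.isfinite(harmonic_mean_lnL(x))

    def test_empty_input_rejected(self):
        with pytest.raises(McmcError):
            harmonic_mean_lnL([])


class TestProposals:
    def _state(self, rng, n_part=2):
        tree = Tree.from_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
        models = [SubstitutionModel.from_family("GTR", gamma_shape=1.0)
                  for _ in range(n_part)]
        return ChainState(tree, models, np.full(n_part, 1.0 / n_part))

    def test_nni_proposal_hits_both_alternatives_evenly(self):
        rng = np.random.default_rng(5)
        cfg = McmcConfig()
        st = self._state(rng)
        base = topology_key(st.tree)
        seen = {}
        for _ in range(3000):
            new, logh, touched = propose(st, "NNI", rng, cfg,
                                         np.array([5.0, 5.0]), Priors())
            assert logh == 0.0
            k = topology_key(new.tree)
            assert k != base
            seen[k] = seen.get(k, 0) + 1
        assert len(seen) == 2
        freqs = np.array(list(seen.values())) / 3000
        assert np.abs(freqs - 0.5).max() < 3 * 0.5 / np.sqrt(3000)

    def test_branch_multiplier_hastings_is_log_m(self):
        rng = np.random.default_rng(9)
        cfg = McmcConfig()
        st = self._state(rng)
        for _ in range(50):
            new, logh, _ = propose(st, "branch-multiplier", rng, cfg,
                                   np.array([5.0, 5.0]), Priors())
            changed = [(k, v) for k, v in new.tree.lengths.items()
                       if abs(v - st.tree.lengths[k]) > 1e-15]
            assert len(changed) == 1
            key, v = changed[0]
            assert logh == pytest.approx(np.log(v / st.tree.lengths[key]))

    def test_dirichlet_moves_stay_on_simplex(self):
        rng = np.random.default_rng(13)
        cfg = McmcConfig()
        st = self._state(rng)
        for move in ("Dirichlet-frequencies", "Dirichlet-exchangeabilities",
                     "multiplier-Dirichlet"):
            for _ in range(20):
                new, logh, _ = propose(st, move, rng, cfg,
                                       np.array([5.0, 5.0]), Priors())
                assert np.isfinite(logh)
                for m in new.models:
                    assert sum(m.base_freqs) == pytest.approx(1.0)
                    assert min(m.base_freqs) >= 0
                assert new.rate_point.sum() == pytest.approx(1.0)


class TestStationarityRule:
    def _trace(self, lnl):
        from mitopart.mcmc import PosteriorTrace
        n = len(lnl)
        return PosteriorTrace(
            McmcConfig(n_generations=1000, burnin_fraction=0.0), "x",
            np.arange(n), np.asarray(lnl, float), np.abs(lnl) / 10.0,
            [("t",)] * n, [None] * n, np.full((n, 1), 1.0),
            np.full((n, 4), 0.25), np.full((n, 1), 1.0))

    def test_good_mixing_accepted(self):
        rng = np.random.default_rng(1)
        trace = self._trace(rng.normal(-100, 1, size=600))
        decision = assess_stationarity(trace)
        assert decision.accept
        assert decision.min_ess >= 100

    def test_sticky_series_requests_doubling(self):
        trace = self._trace(np.repeat(np.arange(30.0), 20) - 700)
        cfg = McmcConfig(n_generations=1000,
                         extension_cap_generations=10_000,
                         burnin_fraction=0.0)
        decision = assess_stationarity(trace, cfg)
        assert not decision.accept
        assert decision.new_n_generations == 2000

    def test_cap_forces_accept_with_warning(self):
        trace = self._trace(np.repeat(np.arange(30.0), 20) - 700)
        cfg = McmcConfig(n_generations=8000,
                         extension_cap_generations=10_000,
                         burnin_fraction=0.0)
        decision = assess_stationarity(trace, cfg)
        assert decision.accept
        assert decision.capped


class TestSampler:
    def test_same_seed_reproduces_trace_exactly(self):
        aln = Alignment.from_sequences([
            ("a", "ACGTACGTAACC"), ("b", "ACGTACTTAACC"),
            ("c", "ACCTACGTATCC"), ("d", "AGGTACGTAACC")])
        scheme = single_partition(12)
        cfg = McmcConfig(n_generations=400, n_chains=2, sample_every=10,
                         seed=77, n_gamma_categories=2)
        t1 = run_mcmc(aln, scheme, "GTR_G", config=cfg)
        t2 = run_mcmc(aln, scheme, "GTR_G", config=cfg)
        assert (t1.lnl == t2.lnl).all()
        assert (t1.tree_length == t2.tree_length).all()
        assert t1.topologies == t2.topologies

    def test_prior_only_branch_length_moments(self):
        """With no data the sampler must reproduce the Exp(0.1) prior."""
        taxa = ["a", "b", "c", "d"]
        aln = Alignment(taxa, np.full((4, 5), "?"))
        cfg = McmcConfig(n_generations=20_000, n_chains=1, sample_every=10,
                         seed=5, n_gamma_categories=1, start_tree="random")
        trace = run_mcmc(aln, single_partition(5), "best_fit",
                         families=["JC"], config=cfg)
        post = trace.post_burnin()
        mean_bl = post.tree_length.mean() / 5.0  # 5 edges on 4 taxa
        assert mean_bl == pytest.approx(0.1, rel=0.15)

    def test_heating_leaves_cold_chain_marginal_unchanged(self):
        """Swaps with heated companions must not distort the cold marginal:
        on a prior-only run the exact target is known, so the heated run's
        cold chain must reproduce the prior's topology uniformity, branch
        mean (5 edges x Exp(0.1)) and branch SD."""
        from collections import Counter

        taxa = ["a", "b", "c", "d"]
        aln = Alignment(taxa, np.full((4, 2), "?"))
        scheme = single_partition(2)
        hot = run_mcmc(aln, scheme, "best_fit", families=["JC"],
                       config=McmcConfig(n_chains=3, n_generations=20_000,
                                         sample_every=20, seed=21,
                                         n_gamma_categories=1,
                                         start_tree="random"))
        post = hot.post_burnin()
        assert post.tree_length.mean() == pytest.approx(0.5, rel=0.10)
        # Exp(0.1) branches: tree-length SD = 0.1 * sqrt(5)
        assert post.tree_length.std() == pytest.approx(0.2236, rel=0.20)
        counts = Counter(post.topologies)
        freqs = np.array(list(counts.values())) / post.n_samples
        assert len(counts) == 3
        assert np.abs(freqs - 1 / 3).max() < 0.08
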