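"""MCMC over inclusion vectors: proposals, acceptance, chains, pooling."""

import math

import numpy as np
import pytest

import bamscan as bs
from bamscan.sampler import ChainState, _move_probs


@pytest.fixture(scope="module")
def paired_data() -> bs.Dataset:
    """nu=4 with two identical column pairs (0,1) and (2,3)."""
    rng = np.random.default_rng(5)
    a = rng.standard_normal(120)
    b = rng.standard_normal(120)
    X = np.column_stack([a, a, b, b])
    y = (rng.random(120) < 0.4).astype(float)
    return bs.Dataset(X, y)


class TestInitialization:
    def test_identical_pairs_never_co_start(self, paired_data):
        cfg = bs.ChainConfig(n_chains=6, seed=1)
        starts = bs.initialize_chains(paired_data, cfg, k_clusters=2, start_size=2)
        for s in starts:
            assert len(s) == 2
            assert s not in [(0, 1), (2, 3)]  # never both of a perfect pair

    def test_start_size_one_is_a_medoid(self, paired_data):
        cfg = bs.ChainConfig(n_chains=3, seed=2)
        starts = bs.initialize_chains(paired_data, cfg, k_clusters=2, start_size=1)
        assert all(len(s) == 1 for s in starts)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 20))
        y = (rng.random(200) < 0.4).astype(float)
        data = bs.Dataset(X, y)
        cfg = bs.ChainConfig(n_chains=8, seed=99)
        a = bs.initialize_chains(data, cfg, k_clusters=4, start_size=5)
        b = bs.initialize_chains(data, cfg, k_clusters=4, start_size=5)
        assert a == b

    def test_rejects_oversized_start(self, paired_data):
        with pytest.raises(ValueError):
            bs.initialize_chains(paired_data, bs.ChainConfig(seed=0), start_size=5)


class TestProposals:
    def test_empty_state_forces_add(self, paired_data):
        rng = np.random.default_rng(0)
        r2 = bs.pairwise_r2(paired_data)
        cfg = bs.ChainConfig(seed=0)
        for _ in range(50):
            s_new, log_ratio, move = bs.propose_move((), rng, 4, cfg, r2)
            assert move == "add" and len(s_new) == 1
            # reverse remove carries weight 9/20 of the full menu
            assert log_ratio == pytest.approx(math.log((9 / 20) / (1 / 4)))

    def test_move_type_frequencies_match_9_9_2(self, paired_data):
        rng = np.random.default_rng(1)
        r2 = bs.pairwise_r2(paired_data)
        cfg = bs.ChainConfig(seed=0)
        counts = {"add": 0, "remove": 0, "swap": 0}
        n = 100_000
        for _ in range(n):
            _, _, move = bs.propose_move((0, 2), rng, 4, cfg, r2)
            counts[move] += 1
        for move, w in [("add", 9 / 20), ("remove", 9 / 20), ("swap", 2 / 20)]:
            se = math.sqrt(w * (1 - w) / n)
            assert abs(counts[move] / n - w) < 3 * se

    def test_swap_prefers_the_identical_twin(self, paired_data):
        """Swapping out one of two identical columns proposes its twin with
        weight r2=1 against eps elsewhere."""
        rng = np.random.default_rng(2)
        r2 = bs.pairwise_r2(paired_data)
        cfg = bs.ChainConfig(seed=0)
        twin = other = 0
        for _ in range(3000):
            s_new, _, move = bs.propose_move((0,), rng, 4, cfg, r2)
            if move != "swap":
                continue
            if s_new == (1,):
                twin += 1
            else:
                other += 1
        assert twin > 0 and other / max(twin, 1) < 0.01

    def test_zero_swap_exponent_makes_replacement_uniform(self, paired_data):
        rng = np.random.default_rng(7)
        r2 = bs.pairwise_r2(paired_data)
        cfg = bs.ChainConfig(seed=0, swap_exponent=0.0)
        counts = {}
        for _ in range(6000):
            s_new, _, move = bs.propose_move((0,), rng, 4, cfg, r2)
            if move == "swap":
                counts[s_new] = counts.get(s_new, 0) + 1
        freqs = np.array(list(counts.values())) / sum(counts.values())
        assert len(counts) == 3
        assert np.abs(freqs - 1 / 3).max() < 0.05

    def test_menu_renormalizes_at_boundaries(self):
        assert _move_probs(0, 4, (9, 9, 2)) == (1.0, 0.0, 0.0)
        assert _move_probs(4, 4, (9, 9, 2)) == (0.0, 1.0, 0.0)
        qa, qr, qs = _move_probs(2, 4, (9, 9, 2))
        assert (qa, qr, qs) == (0.45, 0.45, 0.10)


class TestMHStep:
    def test_collinear_proposal_always_rejected(self, paired_data):
        cache = bs.FitCache(paired_data)
        prior = bs.PriorSpec(0.3, 1, 4, paired_data.n)
        rng = np.random.default_rng(3)
        state = ChainState((0,), cache.log_po((0,), prior), rng)
        for _ in range(20):
            out = bs.mh_step(state, ((0, 1), 0.0, "add"), cache, prior)
            assert out is state  # (0,1) are identical columns: zero likelihood

    def test_symmetric_equal_target_always_accepted(self, paired_data):
        cache = bs.FitCache(paired_data)
        prior = bs.PriorSpec(0.3, 1, 4, paired_data.n)
        rng = np.random.default_rng(4)
        state = ChainState((0,), cache.log_po((0,), prior), rng)
        # the identical twin has the same likelihood and size: delta = 0
        out = bs.mh_step(state, ((1,), 0.0, "swap"), cache, prior)
        assert out.s == (1,)


class TestRunChains:
    def test_same_seed_bit_reproducible(self, paired_data):
        prior = bs.PriorSpec(0.3, 1, 4, paired_data.n)
        cfg = bs.ChainConfig(n_chains=3, burn_in=100, sampling=300, seed=17)
        a = bs.run_chains(paired_data, prior, cfg)
        b = bs.run_chains(paired_data, prior, cfg)
        assert a.draws == b.draws
        assert a.acceptance == b.acceptance

    def test_rejects_zero_sampling(self):
        with pytest.raises(ValueError):
            bs.ChainConfig(sampling=0)

    def test_matches_enumeration_oracle(self, block_data):
        """Detailed balance: pooled model frequencies on an enumerable
        problem match the exact posterior within Monte-Carlo error."""
        data, prior = block_data
        cache = bs.FitCache(data)
        post = bs.enumerate_posterior(data, prior, cache=cache)
        cfg = bs.ChainConfig(n_chains=8, burn_in=1000, sampling=5000, seed=3)
        store = bs.run_chains(data, prior, cfg, cache=cache, start_size=2)
        for j in range(data.nu):
            pp, se = bs.inclusion_probability(store, (j,))
            # a never/always-included variable has zero MCSE; the estimate
            # still carries the 1/N_draws resolution of the pooled sample
            assert abs(pp - post.marginal[j]) <= 3 * se + 1.0 / store.n_total

    def test_dropping_hastings_correction_breaks_the_target(self):
        """Deliberate mutation: accepting with the raw odds ratio only (no
        proposal-asymmetry correction) must provably shift the sampled
        distribution away from the enumeration oracle.  The asymmetry is
        largest at the empty-model boundary, where the move menu
        renormalizes, so the null-model frequency is the statistic."""
        rng0 = np.random.default_rng(21)
        X = rng0.standard_normal((400, 4))
        y = (rng0.random(400) < 0.3).astype(float)
        data = bs.Dataset(X, y)
        prior = bs.PriorSpec(0.5, 1, 4, data.n)
        cache = bs.FitCache(data)
        post = bs.enumerate_posterior(data, prior, cache=cache)
        r2 = bs.pairwise_r2(data)
        cfg = bs.ChainConfig(seed=0)

        def null_freq(seed, use_hastings):
            rng = np.random.default_rng(seed)
            s, lo = (), 0.0
            hits, n_draws = 0, 8000
            for it in range(1000 + n_draws):
                s_new, log_ratio, _ = bs.propose_move(s, rng, data.nu, cfg, r2)
                lo_new = cache.log_po(s_new, prior)
                d = lo_new - lo + (log_ratio if use_hastings else 0.0)
                if lo_new > -math.inf and math.log(rng.random()) < d:
                    s, lo = s_new, lo_new
                if it >= 1000:
                    hits += s == ()
            return hits / n_draws

        exact = post.prob(())
        correct = [null_freq(sd, True) for sd in range(4)]
        mutated = [null_freq(sd, False) for sd in range(4)]
        se_c = np.std(correct, ddof=1) / 2.0
        se_m = np.std(mutated, ddof=1) / 2.0
        assert abs(np.mean(correct) - exact) <= 4 * se_c + 0.01
        assert abs(np.mean(mutated) - exact) > 6 * se_m


class TestMCSE:
    def _store(self, chains):
        draws = [[(0,)] * int(round(m * 10)) + [()] * int(round((1 - m) * 10))
                 for m in chains]
        return bs.SampleStore(draws, 1)

    def test_identical_chains_zero(self):
        assert bs.mcse(self._store([0.5, 0.5, 0.5]), (0,)) == 0.0

    def test_two_point_example(self):
        # chain means 0.4 and 0.6: SD 0.1414 / sqrt(2) = 0.1
        assert bs.mcse(self._store([0.4, 0.6]), (0,)) == pytest.approx(0.1)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            bs.mcse(self._store([0.5]), (0,))

    def test_consistent_with_binomial_theory(self):
        """i.i.d. Bernoulli chains: MCSE within a factor 1.5 of
        sqrt(p(1-p)/N_total)."""
        rng = np.random.default_rng(12)
        p, per_chain, n_chains = 0.3, 2000, 10
        draws = [
            [((0,) if rng.random() < p else ()) for _ in range(per_chain)]
            for _ in range(n_chains)
        ]
        store = bs.SampleStore(draws, 1)
        theory = math.sqrt(p * (1 - p) / (per_chain * n_chains))
        got = bs.mcse(store, (0,))
        assert theory / 1.5 < got < theory * 1.5

    def test_callable_statistic(self):
        store = self._store([0.4, 0.6])
        got = bs.mcse(store, lambda s: float(len(s)))
        assert got == pytest.approx(0.1)


class TestSampleStore:
    def test_roundtrip_serialization(self, tmp_path, block_data):
        data, prior = block_data
        cfg = bs.ChainConfig(n_chains=2, burn_in=50, sampling=200, seed=5)
        store = bs.run_chains(data, prior, cfg, start_size=2)
        path = tmp_path / "draws.tsv.gz"
        store.save(path)
        loaded = bs.SampleStore.load(path, data.nu)
        assert loaded.draws == store.draws

    def test_indicator_matrix_matches_counts(self):
        store = bs.SampleStore([[(0,), (0, 2), ()], [(2,), (), ()]], 3)
        ind = store.indicator_matrix()
        assert ind.shape == (6, 3)
        assert ind.sum(axis=0).tolist() == [2, 0, 2]
        assert store.pooled_inclusion((0, 2)) == pytest.approx(3 / 6)
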