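"""Running-sum enrichment score against brute-force prefix oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirnet.enrichment import combine_es, running_sum_es, score_pair_es
from mirnet.genesets import GeneSet
from mirnet.network import InteractionNetwork
from mirnet.rwr import RankedGeneList, RWRConfig
from mirnet.synthetic import SyntheticSpec, generate


def make_ranking(n: int) -> RankedGeneList:
    order = tuple(f"g{i:03d}" for i in range(n))
    probs = {g: (n - i) / n for i, g in enumerate(order)}
    return RankedGeneList(order, probs)


def brute_force_es(order, query):
    """Independent oracle: evaluate the running sum at every prefix i by
    summing increments from scratch (no cumulative shortcut)."""
    N = len(order)
    members = set(query) & set(order)
    n = len(members)
    best = -np.inf
    for i in range(1, N + 1):
        hits = sum(1 for g in order[:i] if g in members)
        misses = i - hits
        s = hits * (N - n) / n - misses * n / (N - n)
        best = max(best, s)
    return best


class TestRunningSum:
    def test_all_hits_at_top(self):
        """Both query genes at ranks 1-2 of 10: ES = 2*(10-2)/2 = N - n."""
        ranking = make_ranking(10)
        res = running_sum_es(ranking, {"g000", "g001"})
        assert res.es == pytest.approx(8.0)
        assert res.argmax_rank == 2
        assert res.n_set == 2

    def test_all_hits_at_bottom(self):
        """Query at ranks 9-10 of 10: sum falls to -2 by rank 8 then climbs
        by 4 per hit, peaking at N - 2n = 6 at the final prefix."""
        ranking = make_ranking(10)
        res = running_sum_es(ranking, {"g008", "g009"})
        assert res.es == pytest.approx(6.0)
        assert res.argmax_rank == 10

    @given(
        st.integers(min_value=3, max_value=50).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.sets(
                    st.integers(min_value=0, max_value=n - 1),
                    min_size=1, max_size=min(10, n - 1),
                ),
            )
        )
    )
    def test_matches_prefix_oracle(self, case):
        n, positions = case
        ranking = make_ranking(n)
        query = {f"g{i:03d}" for i in positions}
        res = running_sum_es(ranking, query)
        assert res.es == pytest.approx(brute_force_es(ranking.order, query))

    @given(
        st.integers(min_value=4, max_value=40).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.sets(st.integers(min_value=0, max_value=n - 1),
                        min_size=1, max_size=n - 1),
            )
        )
    )
    def test_upper_bound_and_final_prefix(self, case):
        n, positions = case
        ranking = make_ranking(n)
        query = {f"g{i:03d}" for i in positions}
        res = running_sum_es(ranking, query)
        k = len(positions)
        assert res.es <= (n - k) + 1e-9

    def test_depends_only_on_positions(self):
        """Permutation invariance: relabeling genes while keeping the
        query's rank positions fixed leaves ES unchanged."""
        r1 = make_ranking(20)
        order2 = tuple(f"x{i:03d}" for i in range(20))
        r2 = RankedGeneList(order2, {g: (20 - i) / 20 for i, g in enumerate(order2)})
        q1 = {"g003", "g007", "g015"}
        q2 = {"x003", "x007", "x015"}
        assert running_sum_es(r1, q1).es == running_sum_es(r2, q2).es

    def test_out_of_ranking_genes_dropped(self):
        ranking = make_ranking(10)
        with_extra = running_sum_es(ranking, {"g000", "g001", "zz"})
        without = running_sum_es(ranking, {"g000", "g001"})
        assert with_extra == without

    def test_query_outside_ranking_error(self):
        with pytest.raises(ValueError, match="no gene"):
            running_sum_es(make_ranking(5), {"zz"})

    def test_query_is_whole_ranking_error(self):
        ranking = make_ranking(4)
        with pytest.raises(ValueError, match="undefined"):
            running_sum_es(ranking, set(ranking.order))

    def test_all_negative_prefixes_warn_not_clamp(self):
        """Tiny pathological case where the sum never goes positive: the
        (negative) maximum is returned with a warning, no clamping to 0."""
        ranking = make_ranking(3)
        with pytest.warns(UserWarning):
            res = running_sum_es(ranking, {"g001", "g002"})
        assert res.es < 0


class TestCombine:
    def test_default_beta_midpoint(self):
        assert combine_es(4.0, 2.0, 0.5) == pytest.approx(3.0)

    def test_beta_weights_directions(self):
        hi = combine_es(4.0, 2.0, 0.9)
        lo = combine_es(4.0, 2.0, 0.1)
        assert abs(hi - 4.0) < abs(lo - 4.0)

    def test_equal_scores_identity(self):
        for beta in (0.2, 0.5, 0.8):
            assert combine_es(1.7, 1.7, beta) == pytest.approx(1.7)

    @pytest.mark.parametrize("beta", [0.0, 1.0, -0.5, 1.5])
    def test_beta_out_of_range(self, beta):
        with pytest.raises(ValueError):
            combine_es(1.0, 2.0, beta)


class TestScorePair:
    @pytest.fixture
    def small(self):
        data = generate(SyntheticSpec(n_genes=120, n_diseases=2, n_mirnas=4,
                                      targets_per_mirna=8,
                                      disease_module_size=8, rng_seed=9))
        return data

    def test_identical_sets_symmetric(self, small):
        gs = small.diseases["D000"]
        score = score_pair_es(small.network, gs, gs, RWRConfig(), 0.5)
        assert score.es1 == pytest.approx(score.es2)
        assert score.es == pytest.approx(score.es1)

    def test_role_swap_swaps_components(self, small):
        d = small.diseases["D000"]
        t = small.mirnas["mir000"]
        fwd = score_pair_es(small.network, d, t)
        rev = score_pair_es(small.network, t, d)
        assert fwd.es1 == pytest.approx(rev.es2)
        assert fwd.es2 == pytest.approx(rev.es1)

    def test_planted_pair_beats_random_pair(self):
        """Targets adjacent to the disease module score higher than
        uniformly placed targets (median over seeded draws)."""
        deltas = []
        for seed in range(10):
            data = generate(SyntheticSpec(
                n_genes=150, n_diseases=1, n_mirnas=2, targets_per_mirna=10,
                disease_module_size=10, module_cohesion=1.0,
                signal_fraction=1.0, signal_placement="adjacent",
                rng_seed=seed,
            ))
            d = data.diseases["D000"]
            planted = data.mirnas["mir000"]  # frontier targets
            random_m = data.mirnas["mir001"]  # uniform targets
            s_p = score_pair_es(data.network, d, planted).es
            s_r = score_pair_es(data.network, d, random_m).es
            deltas.append(s_p - s_r)
        assert np.median(deltas) > 0
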