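"""Combination enumeration, design rounds, campaigns, and the DE harness."""

import itertools

import numpy as np
import pytest

from thermoplm.design import (AssayRecord, DesignRoundState, OracleScorer,
                              RidgeScorer, enumerate_combinations,
                              evaluate_selection, run_design_campaign,
                              run_design_round, simulate_directed_evolution)
from thermoplm.scoring import Mutation, Variant
from thermoplm.synthetic import make_landscape


def distinct_singles(wild_type, n):
    return [Mutation(i + 1, wild_type[i], "W") for i in range(n)]


class TestEnumeration:
    def test_counts_match_binomial_sums(self, wild_type):
        singles = distinct_singles(wild_type, 4)
        pool = enumerate_combinations(singles, range(2, 5))
        assert len(pool) == 6 + 4 + 1  # C(4,2)+C(4,3)+C(4,4)

    def test_full_powerset_count(self, wild_type):
        singles = distinct_singles(wild_type, 6)
        pool = enumerate_combinations(singles, range(1, 7))
        assert len(pool) == 2 ** 6 - 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_subset_enumeration(self, wild_type, seed):
        """Random instances with position clashes, N <= 12, against a direct
        powerset filter."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        positions = rng.integers(1, 15, size=n)
        singles = [Mutation(int(p), wild_type[p - 1], "W" if i % 2 else "F")
                   for i, p in enumerate(positions)]
        orders = range(2, int(rng.integers(3, 6)))
        pool = enumerate_combinations(singles, orders)
        brute = 0
        for o in orders:
            for combo in itertools.combinations(singles, o):
                if len({m.position for m in combo}) == o:
                    brute += 1
        assert len(pool) == brute
        for v in pool:
            assert len({m.position for m in v.mutations}) == v.order

    def test_same_position_never_cooccurs(self, wild_type):
        singles = [Mutation(3, wild_type[2], "W"),
                   Mutation(3, wild_type[2], "F"),
                   Mutation(7, wild_type[6], "W")]
        pool = enumerate_combinations(singles, [2])
        assert all({m.position for m in v.mutations} == {3, 7} for v in pool)
        assert len(pool) == 2

    def test_cap_subsamples_with_notice(self, wild_type, caplog):
        singles = distinct_singles(wild_type, 12)
        with caplog.at_level("INFO"):
            pool = enumerate_combinations(singles, range(1, 13), cap=100,
                                          rng=np.random.default_rng(0))
        assert len(pool) == 100
        assert "subsampling" in caplog.text

    def test_empty_singles_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinations([], [2])


class TestDesignRound:
    def setup_state(self, wild_type, seed=0):
        ls = make_landscape(wild_type, n_singles=8, seed=seed)
        state = DesignRoundState(wild_type)
        state.add_labels([AssayRecord(Variant((m,)), ls.fitness(Variant((m,))))
                          for m in ls.singles()])
        return ls, state

    def test_perfect_scorer_selects_true_top_k(self, wild_type):
        ls, state = self.setup_state(wild_type)
        quota = [(2, 3, 6)]
        selection = run_design_round(state, OracleScorer(ls), quota)
        pool = enumerate_combinations(ls.singles(), [2, 3])
        labeled = state.labeled_variants() - {str(v) for v, _ in selection}
        truth = sorted((v for v in pool if str(v) not in labeled),
                       key=lambda v: (-ls.mean_fitness(v), str(v)))[:6]
        assert [str(v) for v, _ in selection] == [str(v) for v in truth]

    def test_labeled_variants_never_reselected(self, wild_type):
        ls, state = self.setup_state(wild_type)
        pre = AssayRecord(Variant(tuple(ls.singles()[:2])), 99.0)
        state.add_labels([pre])
        selection = run_design_round(state, OracleScorer(ls), [(2, 2, 5)])
        assert str(pre.variant) not in {str(v) for v, _ in selection}

    def test_round_requires_labels(self, wild_type):
        with pytest.raises(ValueError, match="zero-shot"):
            run_design_round(DesignRoundState(wild_type), None, [(2, 2, 5)])

    def test_training_set_strictly_grows(self, wild_type):
        ls, state = self.setup_state(wild_type)
        sizes = [len(state.training)]
        for _ in range(2):
            selection = run_design_round(state, OracleScorer(ls), [(2, 4, 4)])
            state.add_labels([AssayRecord(v, ls.fitness(v),
                                          round_tag=state.round_index)
                              for v, _ in selection])
            sizes.append(len(state.training))
        assert sizes == sorted(set(sizes))

    def test_additive_limit_matches_zero_shot_ranking(self, wild_type):
        """Without epistasis or noise, the supervised round's ranking over
        2-site variants equals the additive ranking from single effects."""
        ls = make_landscape(wild_type, n_singles=8, seed=3,
                            pair_fraction=0.0, noise_sd=0.0)
        singles = ls.singles()
        records = [AssayRecord(Variant((m,)), ls.fitness(Variant((m,))))
                   for m in singles]
        pool = enumerate_combinations(singles, [2])
        scorer = RidgeScorer(singles, alpha=1e-8).fit(records)
        predicted = scorer.predict(pool)
        additive = [sum(ls.fitness(Variant((m,))) for m in v.mutations)
                    for v in pool]
        assert np.array_equal(np.argsort(-predicted, kind="stable"),
                              np.argsort(-np.asarray(additive),
                                         kind="stable"))


class TestCampaign:
    def test_best_so_far_is_monotone_and_seeded(self, wild_type):
        ls = make_landscape(wild_type, n_singles=12, seed=4)
        r1 = run_design_campaign(wild_type, ls, ls.singles(), seed=0)
        r2 = run_design_campaign(wild_type, ls, ls.singles(), seed=0)
        assert r1.best_so_far == sorted(r1.best_so_far)
        assert r1.to_json() == r2.to_json()

    def test_round_zero_selects_only_singles(self, wild_type):
        ls = make_landscape(wild_type, n_singles=6, seed=5)
        report = run_design_campaign(wild_type, ls, ls.singles(), seed=1)
        assert all(";" not in s["variant"]
                   for s in report.rounds[0]["selections"])

    def test_campaign_beats_best_single_on_epistatic_landscapes(self,
                                                                wild_type):
        """Three rounds of stacking must beat the best labeled single mutant
        in at least 80% of 20 seeded replicates."""
        wins = 0
        for rep in range(20):
            ls = make_landscape(wild_type, n_singles=15, seed=rep)
            best_single = max(ls.fitness(Variant((m,)))
                              for m in ls.singles())
            report = run_design_campaign(wild_type, ls, ls.singles(),
                                         seed=rep)
            wins += report.best_so_far[-1] > best_single
        assert wins >= 16


@pytest.fixture(scope="module")
def de_table(wild_type):
    ls = make_landscape(wild_type, n_singles=8, seed=6)
    return simulate_directed_evolution(ls, replicates=20, rounds=2,
                                       budget=30, seed=2)


class TestDirectedEvolution:

    def test_default_protocol_dimensions(self, wild_type):
        import inspect
        sig = inspect.signature(simulate_directed_evolution)
        assert sig.parameters["replicates"].default == 100
        assert sig.parameters["rounds"].default == 2
        assert sig.parameters["budget"].default == 50

    def test_topk_dominates_random_in_mean_max_fitness(self, de_table):
        final = de_table[de_table["round"] == 2].set_index("sampler")
        assert final.loc["top-k", "mean_max_fitness"] >= \
            final.loc["random", "mean_max_fitness"]

    def test_reproducible_given_seed(self, wild_type, de_table):
        ls = make_landscape(wild_type, n_singles=8, seed=6)
        again = simulate_directed_evolution(ls, replicates=20, rounds=2,
                                            budget=30, seed=2)
        assert again.equals(de_table)

    def test_budget_exceeding_landscape_rejected(self, wild_type):
        ls = make_landscape(wild_type, n_singles=3, seed=0)
        with pytest.raises(ValueError, match="budget"):
            simulate_directed_evolution(ls, replicates=1, budget=100)


class TestSelectionMetrics:
    def test_direct_arithmetic(self):
        m = evaluate_selection([1.2, 0.8, 1.5], 1.0)
        assert (m.n_positive, m.max_fitness, m.median_fitness) == \
            (2, 1.5, 1.2)

    def test_all_below_wild_type(self):
        assert evaluate_selection([0.1, 0.2], 1.0).n_positive == 0

    def test_single_variant(self):
        m = evaluate_selection([2.0], 1.0)
        assert m.max_fitness == m.median_fitness == 2.0

    def test_even_count_median_uses_mean(self):
        assert evaluate_selection([1.0, 2.0, 3.0, 4.0], 0.0).median_fitness \
            == 2.5

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            evaluate_selection([], 1.0)
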