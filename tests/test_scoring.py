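"""Variant parsing, log-odds scoring, saturation scans, filters, selection."""

import logging

import numpy as np
import pandas as pd
import pytest

from thermoplm.model import ModelConfig, ThermoPLM
from thermoplm.scoring import (Mutation, Variant, VariantParseError,
                               exclude_near_sites, log_prob_matrix,
                               make_scorecard, parse_variant, score_saturation,
                               score_single, score_variant, select_top_k)


@pytest.fixture(scope="module")
def model():
    return ThermoPLM(ModelConfig(n_layers=1, n_heads=2, embed_dim=16,
                                 max_len=1024, seed=5))


WT = "MAGCHKLVDE"  # positions 1..10


class TestParsing:
    def test_single_mutation_on_long_sequence(self):
        # mirror of the published notation on a sequence with Q at 786
        wt = ("A" * 785) + "Q" + ("A" * 50)
        v = parse_variant("Q786L", wt)
        assert v.mutations == (Mutation(786, "Q", "L"),)

    def test_multisite_sorted_and_canonical(self):
        v = parse_variant("G5H;A2C", "MAKKGKL")
        assert str(v) == "A2C;G5H"
        assert [m.position for m in v.mutations] == [2, 5]

    def test_colon_dialect_equivalent(self):
        a = parse_variant("A2C;G5H", "MAKKGKL")
        b = parse_variant("A2C : G5H".replace(" ", ""), "MAKKGKL")
        c = parse_variant("A2C: G5H", "MAKKGKL")
        assert str(a) == str(b) == str(c)

    def test_duplicate_position_rejected(self):
        with pytest.raises(VariantParseError, match="duplicate"):
            parse_variant("A2C;A2G", "MAKKGKL")

    def test_wild_type_mismatch_reports_expected_and_found(self):
        with pytest.raises(VariantParseError, match="says G.*has A"):
            parse_variant("G2C", "MAKKGKL")

    def test_malformed_and_empty(self):
        with pytest.raises(VariantParseError):
            parse_variant("A2", "MAKKGKL")
        with pytest.raises(VariantParseError):
            parse_variant("", "MAKKGKL")

    def test_round_trip_canonical_form(self):
        v = parse_variant("K4W;A2C", "MAKKGKL")
        assert str(parse_variant(str(v), "MAKKGKL")) == str(v)


class TestScoreSingle:
    def test_identity_substitution_scores_zero(self, model):
        assert score_single(model, WT, Mutation(3, "G", "G")) == 0.0

    def test_formula_on_known_probabilities(self, model):
        """P(mut)=0.2, P(wt)=0.1 at the site must give exactly ln 2."""
        from thermoplm.vocab import DEFAULT_VOCAB
        logp = np.log(np.full((3, 20), 0.02))
        logp[1, 5], logp[1, 7] = np.log(0.2), np.log(0.1)
        wt = "A" + DEFAULT_VOCAB.symbol(7) + "A"
        mut = Mutation(2, DEFAULT_VOCAB.symbol(7), DEFAULT_VOCAB.symbol(5))
        got = score_single(model, wt, mut, _logp=logp)
        assert got == pytest.approx(np.log(2.0), rel=1e-12)

    def test_matches_distribution_read_directly(self, model):
        toks = model.vocab.encode(WT)
        p = model.mlm_distributions(model.encode(toks))[0]
        mut = Mutation(4, "C", "W")
        expected = np.log(p[3, model.vocab.index("W")]) - \
            np.log(p[3, model.vocab.index("C")])
        assert score_single(model, WT, mut) == pytest.approx(expected,
                                                             rel=1e-9)

    def test_antisymmetry_on_same_pass(self, model):
        toks = model.vocab.encode(WT)
        logp = log_prob_matrix(model, toks)
        fwd = score_single(model, WT, Mutation(6, "K", "R"), _logp=logp)
        mutated = WT[:5] + "R" + WT[6:]
        back = score_single(model, mutated, Mutation(6, "R", "K"), _logp=logp)
        assert fwd == pytest.approx(-back, rel=1e-12)

    def test_position_out_of_range(self, model):
        with pytest.raises(ValueError):
            score_single(model, WT, Mutation(11, "E", "A"))


class TestScoreVariant:
    def test_empty_variant_scores_zero(self, model):
        assert score_variant(model, WT, Variant(())) == 0.0

    def test_additivity_and_order_invariance(self, model):
        v12 = parse_variant("A2C;H5Y", WT)
        v21 = parse_variant("H5Y;A2C", WT)
        s1 = score_single(model, WT, Mutation(2, "A", "C"))
        s2 = score_single(model, WT, Mutation(5, "H", "Y"))
        assert score_variant(model, WT, v12) == pytest.approx(s1 + s2,
                                                              rel=1e-9)
        assert score_variant(model, WT, v21) == \
            pytest.approx(score_variant(model, WT, v12), rel=1e-12)


class TestSaturation:
    def test_row_count_and_consistency(self, model):
        card = score_saturation(model, WT)
        assert len(card) == 19 * len(WT)
        assert sorted(card["rank"]) == list(range(1, len(card) + 1))
        # spot-check a few rows against direct scoring
        for _, row in card.sample(5, random_state=0).iterrows():
            v = parse_variant(row["variant"], WT)
            assert row["score"] == pytest.approx(
                score_single(model, WT, v.mutations[0]), rel=1e-9)

    def test_wt_marginal_uses_one_pass_masked_marginal_L(self, model):
        before = model.n_encode_calls
        score_saturation(model, WT, mode="wt-marginal")
        assert model.n_encode_calls - before == 1
        before = model.n_encode_calls
        score_saturation(model, WT, mode="masked-marginal")
        assert model.n_encode_calls - before == len(WT)

    def test_ensemble_score_is_mean_of_member_scores(self):
        members = [ThermoPLM(ModelConfig(n_layers=1, n_heads=2, embed_dim=16,
                                         seed=s)) for s in (0, 1)]
        mut = Mutation(4, "C", "W")
        per_member = [score_single(m, WT, mut) for m in members]
        assert score_single(members, WT, mut) == \
            pytest.approx(np.mean(per_member), rel=1e-9)


class TestDistanceFilter:
    def make_card(self):
        return make_scorecard(
            [Variant((Mutation(1, "M", "A"),)),
             Variant((Mutation(2, "A", "C"),)),
             Variant((Mutation(3, "G", "H"),))],
            [3.0, 2.0, 1.0], source="t")

    def coords(self, d1, d2, d3):
        return {10: np.array([[0.0, 0.0, 0.0]]),
                1: np.array([[d1, 0.0, 0.0]]),
                2: np.array([[d2, 0.0, 0.0]]),
                3: np.array([[d3, 0.0, 0.0]])}

    def test_boundary_convention(self):
        card = self.make_card()
        out = exclude_near_sites(card, self.coords(5.9, 6.0, 6.1), {10})
        assert list(out["variant"]) == ["G3H"]  # 5.9 and 6.0 excluded

    def test_empty_active_sites_is_identity(self):
        card = self.make_card()
        out = exclude_near_sites(card, {}, set())
        pd.testing.assert_frame_equal(out, card)

    def test_missing_active_site_coordinates_rejected(self):
        with pytest.raises(ValueError, match="active-site"):
            exclude_near_sites(self.make_card(), {1: np.zeros((1, 3))}, {99})

    def test_candidate_without_coordinates_retained_with_warning(self, caplog):
        coords = self.coords(1.0, 1.0, 1.0)
        del coords[3]
        with caplog.at_level(logging.WARNING):
            out = exclude_near_sites(self.make_card(), coords, {10})
        assert list(out["variant"]) == ["G3H"]
        assert "retained" in caplog.text


class TestSelectTopK:
    def test_plain_top_k(self):
        card = make_scorecard([Variant((Mutation(1, "M", "A"),)),
                               Variant((Mutation(2, "A", "C"),)),
                               Variant((Mutation(3, "G", "H"),))],
                              [3.0, 1.0, 2.0])
        out = select_top_k(card, 2)
        assert list(out["variant"]) == ["M1A", "G3H"]

    def test_ties_break_lexicographically(self):
        card = make_scorecard([Variant((Mutation(2, "A", "C"),)),
                               Variant((Mutation(1, "M", "A"),))],
                              [1.0, 1.0])
        out = select_top_k(card, 2)
        assert list(out["variant"]) == ["A2C", "M1A"]

    def test_k_exceeding_pool_returns_pool(self):
        card = make_scorecard([Variant((Mutation(1, "M", "A"),))], [1.0])
        assert len(select_top_k(card, 10)) == 1

    def test_per_order_quotas(self, rng):
        variants, scores = [], []
        wt = "MAGCHKLVDEMAGCHKLVDE"
        muts = [Mutation(i + 1, wt[i], "W") for i in range(15)]
        for order in (2, 3, 4):
            for start in range(12):
                variants.append(Variant(tuple(muts[start:start + order])))
                scores.append(float(rng.normal()))
        card = make_scorecard(variants, scores)
        out = select_top_k(card, 30, quota_per_order={2: 10, 3: 10, 4: 10})
        counts = out["n_mutations"].value_counts().to_dict()
        assert all(v <= 10 for v in counts.values())
        assert set(counts) <= {2, 3, 4}
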