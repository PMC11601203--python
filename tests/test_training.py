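"""Training-protocol contracts: scheduling, freezing, determinism, epochs."""

import numpy as np
import pytest

from thermoplm.model import ModelConfig, ThermoPLM
from thermoplm.synthetic import (FamilyModel, SyntheticOgtModel,
                                 make_landscape, make_ogt_corpus)
from thermoplm.training import (PretrainConfig, RegressorConfig,
                                SupervisedRegressor, TrainedEnsemble,
                                average_epochs, ensemble_average,
                                finetune_homologs, fit_regressor,
                                mean_mlm_loss, pretrain_alternating)

WT = "MKVLITGAGSGIGLELVKQLLAEGHEVIALDRSEEKLQAL"  # 40 residues
TINY = ModelConfig(n_layers=1, n_heads=2, embed_dim=16, max_len=64, seed=0)


def small_corpus(n=30, seed=0):
    return make_ogt_corpus(FamilyModel(consensus=WT, seed=seed),
                           SyntheticOgtModel(), n, seed)


class TestPretraining:
    def test_round_robin_never_starves_a_task(self):
        corpus = small_corpus(12)
        cfg = PretrainConfig(total_steps=9, tokens_per_microbatch=128,
                             n_alignment_mutants=4, seed=0)
        _, log = pretrain_alternating(corpus, cfg, model_config=TINY)
        tasks = [e["task"] for e in log if "task" in e]
        assert tasks.count("mlm") == tasks.count("ogt") == \
            tasks.count("corr") == 3
        for t in ("mlm", "ogt", "corr"):
            hits = [i for i, task in enumerate(tasks) if task == t]
            assert max(np.diff(hits)) <= 3

    def test_same_seed_reproduces_checkpoints(self):
        corpus = small_corpus(10)
        cfg = PretrainConfig(total_steps=6, tokens_per_microbatch=128,
                             n_alignment_mutants=4, seed=11)
        m1, log1 = pretrain_alternating(corpus, cfg, model_config=TINY)
        m2, log2 = pretrain_alternating(corpus, cfg, model_config=TINY)
        for name in m1.parameter_names():
            assert np.array_equal(m1.params[name].data, m2.params[name].data)
        assert log1 == log2

    def test_overlong_sequences_skipped_with_count(self):
        corpus = small_corpus(5) + [("long", "A" * 100, 50.0)]
        cfg = PretrainConfig(total_steps=3, tokens_per_microbatch=128,
                             n_alignment_mutants=4)
        _, log = pretrain_alternating(corpus, cfg, model_config=TINY)
        assert log[0]["n_skipped"] == 1
        assert log[0]["n_sequences"] == 5

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            pretrain_alternating([], PretrainConfig(), model_config=TINY)

    def test_memorization_drives_loss_below_point_one(self):
        """A 2-layer, d=64 model memorizes a 10-sequence corpus: the running
        MLM training loss falls below 0.1 (perfect reconstruction is 0)."""
        corpus = make_ogt_corpus(
            FamilyModel(consensus=WT[:30], seed=0), SyntheticOgtModel(),
            10, 0)
        seqs = [s for _, s, _ in corpus]
        model = ThermoPLM(ModelConfig(n_layers=2, n_heads=4, embed_dim=64,
                                      max_len=64, seed=0))
        model, log = finetune_homologs(model, seqs, steps=2000,
                                       learning_rate=1e-3, seed=0)
        losses = [e["loss"] for e in log if "loss" in e]
        assert float(np.mean(losses[-25:])) < 0.1

    def test_training_reduces_mlm_loss(self):
        """A tiny model must roughly halve its reconstruction loss on a
        10-sequence corpus it can memorize."""
        seqs = [seq for _, seq, _ in small_corpus(10)]
        model = ThermoPLM(ModelConfig(n_layers=2, n_heads=4, embed_dim=64,
                                      max_len=64, seed=0))
        initial = mean_mlm_loss(model, seqs, seed=1)
        model, _ = finetune_homologs(model, seqs, steps=150,
                                     learning_rate=1e-3, seed=0)
        final = mean_mlm_loss(model, seqs, seed=1)
        assert final < 0.5 * initial


class TestHomologFinetuning:
    def test_ogt_head_untouched_bit_for_bit(self):
        model = ThermoPLM(TINY)
        before = {n: model.params[n].data.copy()
                  for n in model.ogt_head_parameter_names()}
        seqs = [seq for _, seq, _ in small_corpus(8)]
        model, _ = finetune_homologs(model, seqs, steps=5, seed=0)
        for n, arr in before.items():
            assert np.array_equal(model.params[n].data, arr)

    def test_homolog_cap_truncates_to_first_30000(self):
        model = ThermoPLM(ModelConfig(n_layers=1, n_heads=2, embed_dim=16,
                                      max_len=16, seed=0))
        homologs = ["MKVLITGAGS"] * 35_000
        _, log = finetune_homologs(model, homologs, steps=1,
                                   tokens_per_microbatch=32, seed=0)
        assert log[0]["n_sequences"] == 30_000

    def test_finetuning_lowers_family_mlm_loss(self):
        from thermoplm.synthetic import generate_family
        family = generate_family(FamilyModel(consensus=WT, rates=0.02,
                                             seed=3), 20)
        model = ThermoPLM(TINY)
        before = mean_mlm_loss(model, family, seed=2)
        model, _ = finetune_homologs(model, family, steps=60,
                                     learning_rate=1e-3, seed=0)
        assert mean_mlm_loss(model, family, seed=2) < before

    def test_empty_homolog_set_rejected(self):
        with pytest.raises(ValueError):
            finetune_homologs(ThermoPLM(TINY), [])


class TestDynamicEpochs:
    @pytest.mark.parametrize("stops,expected", [
        ([10, 10, 10, 10, 10], 10),
        ([8, 12, 10, 9, 11], 10),
        ([1, 1, 1, 1, 2], 1),   # mean 1.2 rounds down
        ([2, 3, 3, 2, 3], 3),   # mean 2.6 rounds up
        ([0], 1),               # floored at one epoch
    ])
    def test_round_half_up_mean(self, stops, expected):
        assert average_epochs(stops) == expected

    def test_fewer_records_than_folds_rejected(self, tiny_model, wild_type):
        reg = SupervisedRegressor(tiny_model, wild_type,
                                  RegressorConfig(folds=5))
        from thermoplm.scoring import Variant
        ls = make_landscape(wild_type, n_singles=3, seed=0)
        records = [(Variant((m,)), 1.0) for m in ls.singles()]
        with pytest.raises(ValueError, match="folds"):
            reg.determine_epochs(records)


class TestSupervisedRegressor:
    def make_records(self, wild_type, seed=0, n=40):
        from thermoplm.design import enumerate_combinations
        ls = make_landscape(wild_type, n_singles=10, seed=seed,
                            pair_fraction=0.0, noise_sd=0.0)
        pool = enumerate_combinations(ls.singles(), [1, 2])
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(pool))
        train = [(pool[i], ls.fitness(pool[i])) for i in idx[:n]]
        test = [(pool[i], ls.fitness(pool[i])) for i in idx[n:n + 30]]
        return train, test

    def test_backbone_frozen_and_head_rerandomized(self, tiny_model,
                                                   wild_type):
        train, _ = self.make_records(wild_type)
        reg = fit_regressor(tiny_model, wild_type, train,
                            RegressorConfig(seed=1, max_epochs=25,
                                            patience=5))
        head = {"fc3_W", "fc3_b", "fc4_W", "fc4_b"}
        for name in tiny_model.parameter_names():
            same = np.array_equal(reg.model.params[name].data,
                                  tiny_model.params[name].data)
            if name in ("fc3_W", "fc4_W"):
                assert not same  # rerandomized then trained
            elif name not in head:
                assert same  # frozen bit-for-bit
        # gradients structurally cannot reach the backbone
        for name in tiny_model.parameter_names():
            if name not in head:
                assert reg.model.params[name].grad is None

    def test_training_reduces_mse_from_initialization(self, tiny_model,
                                                      wild_type):
        train, _ = self.make_records(wild_type)
        reg = SupervisedRegressor(tiny_model, wild_type,
                                  RegressorConfig(seed=2))
        X = reg._standardize(reg.features([v for v, _ in train]), fit=True)
        y = reg._zscore_fit([f for _, f in train])
        mse0 = float(np.mean((reg._forward_head(X).data - y) ** 2))
        reg.fit(train)
        pred = (reg.predict([v for v, _ in train]) - reg.label_mean) \
            / reg.label_sd
        assert float(np.mean((pred - y) ** 2)) < mse0

    def test_recovers_additive_landscape_ranking(self, tiny_model,
                                                 wild_type):
        """40 noise-free additive labels: held-out rank correlation > 0 in
        at least 9 of 10 seeded repeats."""
        from scipy.stats import spearmanr
        wins = 0
        for seed in range(10):
            train, test = self.make_records(wild_type, seed=100 + seed)
            reg = fit_regressor(tiny_model, wild_type, train,
                                RegressorConfig(seed=seed))
            rho = spearmanr(reg.predict([v for v, _ in test]),
                            [f for _, f in test]).statistic
            wins += rho > 0
        assert wins >= 9


class TestEnsemble:
    def test_mean_and_identity(self):
        assert ensemble_average([{"A2C": 2.0}, {"A2C": 4.0}]) == {"A2C": 3.0}
        assert ensemble_average([{"A2C": 5.0}]) == {"A2C": 5.0}

    def test_permutation_invariance(self, rng):
        tables = [{f"v{i}": float(rng.normal()) for i in range(5)}
                  for _ in range(4)]
        fwd = ensemble_average(tables)
        rev = ensemble_average(tables[::-1])
        assert fwd.keys() == rev.keys()
        for k in fwd:
            assert fwd[k] == pytest.approx(rev[k], rel=1e-12)

    def test_missing_variant_rejected_by_name(self):
        with pytest.raises(ValueError, match="A2C"):
            ensemble_average([{"A2C": 1.0, "G5H": 2.0}, {"G5H": 2.0}])

    def test_trained_ensemble_requires_members(self):
        with pytest.raises(ValueError):
            TrainedEnsemble([])
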