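import numpy as np
import pytest

from mirloc import nn
from mirloc.model import (
    MirnaLocalizationModel,
    ModelConfig,
    bce_loss,
    modality_gate,
    multi_head_cross_attention,
)

from .oracles import attention_loops


class TestBceLoss:
    def test_uninformative_prediction_costs_ln2(self):
        assert bce_loss(np.array([[1]]), np.array([[0.5]])) == pytest.approx(np.log(2))

    def test_confident_correct_prediction_near_zero(self):
        y = np.array([[1, 0]])
        assert bce_loss(y, np.array([[1.0, 0.0]])) == pytest.approx(0.0, abs=1e-5)

    def test_hand_evaluated_example(self):
        got = bce_loss(np.array([[1, 0]]), np.array([[0.9, 0.2]]))
        assert got == pytest.approx(-(np.log(0.9) + np.log(0.8)), abs=1e-12)

    def test_sample_average_sums_over_compartments(self):
        y = np.array([[1, 0], [0, 1]])
        p = np.full((2, 2), 0.5)
        assert bce_loss(y, p, "samples") == pytest.approx(2 * np.log(2))
        assert bce_loss(y, p, "elements") == pytest.approx(np.log(2))

    def test_true_labels_are_the_global_minimum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, size=(6, 7))
            p = rng.uniform(0.01, 0.99, size=(6, 7))
            assert bce_loss(y, y.astype(float)) <= bce_loss(y, p)


class TestGate:
    def test_equal_logits_give_uniform_weights(self):
        h = nn.Tensor(np.ones((3, 4, 8)))
        a, _ = modality_gate(h, nn.Tensor(np.zeros((8, 1))), nn.Tensor(np.zeros(1)))
        assert np.allclose(a.data, 0.25)

    def test_weights_sum_to_one_per_mirna(self):
        rng = np.random.default_rng(1)
        h = nn.Tensor(rng.normal(size=(5, 3, 8)))
        a, sel = modality_gate(h, nn.Tensor(rng.normal(size=(8, 1))),
                               nn.Tensor(rng.normal(size=1)))
        assert np.allclose(a.data.sum(axis=1), 1.0)
        assert sel.shape == h.shape

    def test_dominant_logit_takes_all_weight(self):
        h = nn.Tensor(np.stack([np.full((2, 4), 50.0), np.zeros((2, 4))], axis=1))
        a, _ = modality_gate(h, nn.Tensor(np.ones((4, 1))), nn.Tensor(np.zeros(1)))
        assert a.data[:, 0, 0] == pytest.approx(1.0, abs=1e-6)


class TestCrossAttention:
    def _weights(self, rng, d):
        return [nn.Tensor(rng.normal(size=(d, d))) for _ in range(4)]

    def test_single_token_attention_weight_is_one(self):
        rng = np.random.default_rng(2)
        d = 4
        wq, wk, wv, wo = self._weights(rng, d)
        x = rng.normal(size=(3, 1, d))
        out = multi_head_cross_attention(nn.Tensor(x), nn.Tensor(x), nn.Tensor(x),
                                         wq, wk, wv, wo, n_heads=2)
        want = (x @ wv.data) @ wo.data  # softmax over one token is exactly 1
        assert np.allclose(out.data, want, atol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        d, heads = 8, 2
        wq, wk, wv, wo = self._weights(rng, d)
        q = rng.normal(size=(2, 3, d))
        kv = rng.normal(size=(2, 3, d))
        out = multi_head_cross_attention(nn.Tensor(q), nn.Tensor(kv), nn.Tensor(kv),
                                         wq, wk, wv, wo, heads)
        want = attention_loops(q, kv, kv, wq.data, wk.data, wv.data, wo.data, heads)
        assert np.allclose(out.data, want, atol=1e-6)

    def test_indivisible_head_count_is_an_error(self):
        with pytest.raises(Exception):
            ModelConfig(d_model=10, n_heads=4)


class TestTraining:
    def test_training_loss_decreases_on_planted_signal(self, tiny_bundle):
        synth, bundle = tiny_bundle
        cfg = ModelConfig(d_model=32, epochs=12, patience=12, lr=0.003)
        res = MirnaLocalizationModel(bundle, synth.dataset.labels, cfg).fit(seed=0)
        assert res.history[9]["train_loss"] < res.history[0]["train_loss"]

    def test_same_seed_reproduces_parameters_bitwise(self, tiny_bundle):
        synth, bundle = tiny_bundle
        cfg = ModelConfig(d_model=32, epochs=4, patience=4)
        r1 = MirnaLocalizationModel(bundle, synth.dataset.labels, cfg).fit(seed=7)
        r2 = MirnaLocalizationModel(bundle, synth.dataset.labels, cfg).fit(seed=7)
        for k in r1.params:
            assert np.array_equal(r1.params[k], r2.params[k]), k

    def test_prediction_is_deterministic_and_in_open_interval(self, tiny_bundle):
        synth, bundle = tiny_bundle
        cfg = ModelConfig(d_model=32, epochs=3, patience=3)
        res = MirnaLocalizationModel(bundle, synth.dataset.labels, cfg).fit(seed=0)
        p1 = res.predict_proba()
        p2 = res.predict_proba()
        assert np.array_equal(p1, p2)
        assert p1.shape == (synth.dataset.n_mirna, 7)
        assert (p1 > 0).all() and (p1 < 1).all()

    def test_constant_labels_converge_to_prevalence(self, tiny_bundle):
        synth, bundle = tiny_bundle
        from mirloc.datamodel import LocalizationMatrix

        n = synth.dataset.n_mirna
        labels = np.zeros((n, 7), dtype=np.int8)
        labels[:, 0] = 1  # cytoplasm always, everything else never
        const = LocalizationMatrix(synth.dataset.labels.entity_ids, labels)
        cfg = ModelConfig(d_model=32, epochs=150, patience=150, lr=0.005, dropout=0.0)
        res = MirnaLocalizationModel(bundle, const, cfg).fit(seed=0)
        p = res.predict_proba()
        assert p[:, 0].mean() > 0.9
        assert p[:, 1:].mean() < 0.1

    def test_ablation_flags_change_the_wiring(self, tiny_bundle):
        synth, bundle = tiny_bundle
        cfg = ModelConfig(d_model=32, epochs=2, patience=2,
                          ablation=frozenset({"no_mrna", "no_loc"}))
        model = MirnaLocalizationModel(bundle, synth.dataset.labels, cfg)
        res = model.fit(seed=0)
        assert not any(k.startswith(("proj_w_mrna", "hg_mrna")) for k in res.params)

    def test_summary_mentions_branches_and_epochs(self, tiny_bundle):
        synth, bundle = tiny_bundle
        cfg = ModelConfig(d_model=32, epochs=2, patience=2)
        res = MirnaLocalizationModel(bundle, synth.dataset.labels, cfg).fit(seed=0)
        text = res.summary()
        assert "mrna_loc" in text and "epochs run" in text


def test_checkpoint_round_trip(tiny_bundle, tmp_path):
    from mirloc.model import load_results

    synth, bundle = tiny_bundle
    cfg = ModelConfig(d_model=32, epochs=2, patience=2)
    model = MirnaLocalizationModel(bundle, synth.dataset.labels, cfg)
    res = model.fit(seed=0)
    res.save(tmp_path / "ckpt")
    loaded = load_results(tmp_path / "ckpt", model)
    # %.10g round-trip keeps ~10 significant digits
    assert np.allclose(loaded.predict_proba(), res.predict_proba(), atol=1e-7)
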