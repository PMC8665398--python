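"""Fusion model forward pass, training, distillation and ensembling."""

import numpy as np
import pytest

from graphsts import model as M
from graphsts.augmentation import SentenceRecord
from graphsts.errors import InputError
from graphsts.graph_encoder import encode_graph, normalized_adjacency
from graphsts.terminology import InducedGraph
from graphsts.text_encoder import (TextEncoderConfig, build_vocab,
                                   encode_ids_batch, pair_ids)

VOCAB = build_vocab(["alpha beta gamma delta", "epsilon zeta eta theta"])
TEXT_CONFIG = TextEncoderConfig(output_dim=8, embedding_dim=8, n_blocks=1,
                                max_len=10)


def tiny_graph(n=2):
    if n == 0:
        return InducedGraph()
    ids = [f"C{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return InducedGraph(node_ids=ids, adjacency=adj, seed_ids=ids)


def tiny_model(seed=0, graph_enabled=True):
    return M.create_fusion_model(
        vocab=VOCAB, text_config=TEXT_CONFIG, gcn_dims=[4, 6, 6],
        head_hidden=5, feature_mode="random", feature_dim=4,
        graph_enabled=graph_enabled, seed=seed)


def tiny_items(n=4, seed=3):
    rng = np.random.default_rng(seed)
    words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
    items = []
    for i in range(n):
        t1 = " ".join(rng.choice(words, size=3))
        t2 = " ".join(rng.choice(words, size=3))
        rec = SentenceRecord(f"r{i}", t1, t2,
                             score=float(np.round(rng.uniform(0, 5), 2)))
        items.append((rec, tiny_graph(2), tiny_graph(3)))
    return items


class TestForward:
    def test_zero_head_weights_return_bias(self):
        model = tiny_model()
        model.head_w2.data[:] = 0.0
        model.head_b2.data[:] = 1.75
        rec = SentenceRecord("r", "alpha beta", "gamma", score=1.0)
        assert M.forward(model, rec, tiny_graph(2), tiny_graph(0)) == \
            pytest.approx(1.75)

    def test_empty_graphs_leave_only_text_and_bias(self):
        model = tiny_model()
        rec = SentenceRecord("r", "alpha beta", "gamma", score=1.0)
        s_empty = M.forward(model, rec, tiny_graph(0), tiny_graph(0))
        model_off = tiny_model(graph_enabled=False)
        for t_src, t_dst in zip(tiny_model().graph_and_head_tensors(),
                                model_off.graph_and_head_tensors()):
            t_dst.data[:] = t_src.data
        s_off = M.forward(model_off, rec, tiny_graph(2), tiny_graph(2))
        assert s_empty == pytest.approx(s_off)

    def test_matches_step_by_step_composition_oracle(self):
        model = tiny_model(seed=5)
        rec = SentenceRecord("r", "alpha beta gamma", "delta epsilon",
                             score=2.0)
        g1, g2 = tiny_graph(3), tiny_graph(2)
        got = M.forward(model, rec, g1, g2)
        # independent recomputation from the pieces
        ids = pair_ids(rec.text1, rec.text2, VOCAB, TEXT_CONFIG.max_len)
        text_vec = encode_ids_batch(ids[None, :], model.text_params,
                                    TEXT_CONFIG).data[0]

        def gvec(g):
            h = model.node_features(g)
            if model.gcn_params.input_projection is not None:
                h = h @ model.gcn_params.input_projection.data
            for w in model.gcn_params.layer_weights:
                h = np.maximum(
                    normalized_adjacency(g.adjacency) @ h @ w.data, 0.0)
            return h.mean(axis=0)

        fused = np.concatenate([text_vec, gvec(g1), gvec(g2)])
        hidden = np.maximum(fused @ model.head_w1.data
                            + model.head_b1.data, 0.0)
        expected = float((hidden @ model.head_w2.data
                          + model.head_b2.data)[0])
        assert got == pytest.approx(expected, abs=1e-6)

    def test_concat_dimension_invariant(self):
        model = tiny_model()
        assert model.concat_dim() == 8 + 2 * 6
        assert model.head_w1.data.shape[0] == model.concat_dim()


class TestBoundedRegressionLoss:
    def test_perfect_student_is_zero_loss(self):
        assert M.bounded_regression_loss(2.0, 3.7, 2.0, m=0.0) == 0.0

    def test_bound_inactive_when_student_beats_teacher(self):
        # student error 0.01, teacher error 1.0, margin 0.5
        loss = M.bounded_regression_loss(2.1, 3.0, 2.0, m=0.5, nu=10.0)
        assert loss == pytest.approx((2.1 - 2.0) ** 2)

    def test_grid_matches_piecewise_oracle(self):
        vals = np.linspace(0, 5, 6)
        margins = [0.0, 0.25, 1.0]
        nus = [0.0, 0.5, 2.0]
        count = 0
        for s in vals:
            for t in vals:
                for g in vals:
                    for m in margins:
                        for nu in nus:
                            got = M.bounded_regression_loss(s, t, g, m, nu)
                            b = (s - t) ** 2 if (s - g) ** 2 + m > \
                                (t - g) ** 2 else 0.0
                            assert got == (s - g) ** 2 + nu * b
                            count += 1
        assert count >= 1000


class TestTraining:
    def test_single_record_overfits(self):
        model = tiny_model(seed=1)
        items = tiny_items(1)
        config = M.TrainConfig(lr_text=1e-2, lr_graph=1e-2, epochs=200,
                               batch_size=1, shuffle_seed=0)
        _, trace = M.train(model, items, config)
        assert trace[-1] < 1e-2

    def test_identical_seeds_identical_traces(self):
        config = M.TrainConfig(epochs=3, batch_size=2, shuffle_seed=9)
        _, trace_a = M.train(tiny_model(seed=2), tiny_items(6), config)
        _, trace_b = M.train(tiny_model(seed=2), tiny_items(6), config)
        assert trace_a == trace_b

    def test_missing_gold_score_rejected(self):
        items = [(SentenceRecord("r", "alpha", "beta"), tiny_graph(1),
                  tiny_graph(1))]
        with pytest.raises(InputError):
            M.train(tiny_model(), items)

    def test_empty_dataset_rejected(self):
        with pytest.raises(InputError):
            M.train(tiny_model(), [])


class TestDistill:
    def _teacher(self, items, value=None):
        return {r.record_id: (r.score if value is None else value)
                for r, _, _ in items}

    def test_nu_zero_matches_plain_training_trajectory(self):
        items = tiny_items(6)
        config = M.TrainConfig(epochs=3, batch_size=2, shuffle_seed=4)
        _, mse_trace = M.train(tiny_model(seed=3), items, config)
        dcfg = M.DistillConfig(teacher_predictions=self._teacher(items),
                               nu=0.0)
        _, kd_trace = M.distill(tiny_model(seed=3), items, config, dcfg)
        assert np.allclose(mse_trace, kd_trace)

    def test_gold_teacher_bound_never_below_mse(self):
        # teacher == gold: B = (s - gold)^2 whenever student is imperfect
        # (m = 0), so the bounded loss dominates plain MSE pointwise
        rng = np.random.default_rng(0)
        for _ in range(200):
            s, g = rng.uniform(0, 5, size=2)
            loss = M.bounded_regression_loss(s, g, g, m=0.0, nu=0.5)
            assert loss >= (s - g) ** 2
            if s != g:
                assert loss == pytest.approx((s - g) ** 2 * 1.5)

    def test_missing_teacher_prediction_rejected(self):
        items = tiny_items(3)
        dcfg = M.DistillConfig(
            teacher_predictions={items[0][0].record_id: 1.0})
        with pytest.raises(InputError):
            M.distill(tiny_model(), items, M.TrainConfig(), dcfg)


class TestEnsemble:
    def test_single_member_is_identity(self):
        model = tiny_model(seed=6)
        items = tiny_items(4)
        solo = M.predict(model, items)
        ens = M.ensemble_predict([model], items)
        assert all(a.score == pytest.approx(b.score)
                   for a, b in zip(solo, ens))

    def test_k_copies_equal_one_model(self):
        model = tiny_model(seed=6)
        items = tiny_items(4)
        ens = M.ensemble_predict([model, model, model], items)
        solo = M.predict(model, items)
        assert all(a.score == pytest.approx(b.score)
                   for a, b in zip(solo, ens))

    def test_mean_then_clamp_ordering(self):
        class Fixed:
            def __init__(self, value):
                self.value = value

            def raw_scores(self, dataset):
                return np.full(len(dataset), self.value)

        items = tiny_items(1)
        preds = M.ensemble_predict([Fixed(1.0), Fixed(2.0), Fixed(6.0)],
                                   items)
        # raw member scores are averaged before any clamping: (1+2+6)/3
        assert preds[0].score == pytest.approx(3.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(InputError):
            M.ensemble_predict([], tiny_items(1))

    def test_predictions_clamped_to_rubric(self):
        class Fixed:
            def raw_scores(self, dataset):
                return np.full(len(dataset), 7.3)

        preds = M.ensemble_predict([Fixed()], tiny_items(2))
        assert all(p.score == 5.0 for p in preds)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = tiny_model(seed=8)
        items = tiny_items(5)
        M.train(model, items, M.TrainConfig(epochs=2, batch_size=2))
        path = tmp_path / "model.json"
        M.save_model(model, path)
        back = M.load_model(path)
        a = [p.score for p in M.predict(model, items)]
        b = [p.score for p in M.predict(back, items)]
        assert np.allclose(a, b)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        M.save_model(tiny_model(), path)
        import json
        blob = json.loads(path.read_text())
        blob["format_version"] = 99
        path.write_text(json.dumps(blob))
        with pytest.raises(Exception):
            M.load_model(path)
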