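import numpy as np
import pytest

from linkseg.graph import GraphConfig, build_dataset
from linkseg.embeddings import reference_embedding
from linkseg.model import (
    ModelConfig,
    TrainedModel,
    TrainingError,
    attention_message_pass,
    edge_geometry,
    init_params,
    score_link,
    train,
)
from linkseg.nn import Tensor


def _layer_params(rng, d, h):
    dh = d // h
    from linkseg.nn import parameter

    return {
        "Wq": parameter(rng.normal(size=(d, d)) / np.sqrt(d)),
        "Wk": parameter(rng.normal(size=(d, d)) / np.sqrt(d)),
        "Wv": parameter(rng.normal(size=(d, d)) / np.sqrt(d)),
        "a_q": parameter(rng.normal(size=(h, dh))),
        "a_k": parameter(rng.normal(size=(h, dh))),
        "wd": parameter(np.zeros(h)),
        "Wo": parameter(rng.normal(size=(d, d)) / np.sqrt(d)),
    }


class TestAttention:
    def test_single_incoming_edge_weight_is_one(self):
        rng = np.random.default_rng(0)
        h = Tensor(rng.normal(size=(3, 8)))
        params = _layer_params(rng, 8, 2)
        _, alpha = attention_message_pass(
            h, h, np.array([1]), np.array([0]), np.array([1.0]), params, 2,
            return_attention=True,
        )
        np.testing.assert_allclose(alpha, 1.0)

    def test_identical_keys_split_evenly(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(3, 8))
        h[2] = h[1]  # two identical source nodes
        params = _layer_params(rng, 8, 2)
        _, alpha = attention_message_pass(
            Tensor(h), Tensor(h), np.array([1, 2]), np.array([0, 0]),
            np.array([2.0, 2.0]), params, 2, return_attention=True,
        )
        np.testing.assert_allclose(alpha, 0.5, atol=1e-12)

    def test_weights_sum_to_one_against_dense_softmax(self):
        rng = np.random.default_rng(2)
        n, d, heads = 20, 16, 4
        h = Tensor(rng.normal(size=(n, d)))
        src = rng.integers(0, n, size=60)
        dst = rng.integers(0, n, size=60)
        dist = rng.uniform(0, 5, size=60)
        params = _layer_params(rng, d, heads)
        _, alpha = attention_message_pass(
            h, h, src, dst, dist, params, heads, return_attention=True
        )
        for node in np.unique(dst):
            np.testing.assert_allclose(alpha[dst == node].sum(axis=0), 1.0, atol=1e-6)

    def test_isolated_nodes_keep_state(self):
        rng = np.random.default_rng(3)
        h = Tensor(rng.normal(size=(4, 8)))
        params = _layer_params(rng, 8, 2)
        out = attention_message_pass(
            h, h, np.array([1]), np.array([0]), np.array([1.0]), params, 2
        )
        np.testing.assert_array_equal(out.data[1:], h.data[1:])


class TestScoreLink:
    def test_zero_vectors_give_half(self):
        assert score_link(np.zeros(4), np.zeros(4)) == 0.5

    def test_aligned_large_vectors_saturate(self):
        z = np.zeros(8)
        z[0] = 10.0
        assert score_link(z, z) > 0.999

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert score_link(a, b) == score_link(b, a)

    def test_monotone_in_dot_product(self):
        e = np.zeros(4)
        e[0] = 1.0
        scores = [score_link(c * e, e) for c in np.linspace(-3, 3, 13)]
        assert all(s1 < s2 for s1, s2 in zip(scores, scores[1:]))


@pytest.fixture(scope="module")
def toy_setup(tissue_small):
    emb = reference_embedding(tissue_small.reference, d=3)
    cfg = GraphConfig()
    _, graphs, stats = build_dataset(tissue_small.transcripts, tissue_small.nuclei, emb, cfg)
    return graphs, emb, cfg, stats


class TestTraining:
    def test_loss_decreases_on_separable_toy(self, toy_setup):
        graphs, emb, cfg, stats = toy_setup
        model = train(graphs, ModelConfig(epochs=8, seed=0), emb, cfg, stats)
        hist = model.history
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]

    def test_same_seed_bitwise_identical_history(self, toy_setup):
        graphs, emb, cfg, stats = toy_setup
        a = train(graphs, ModelConfig(epochs=4, seed=1), emb, cfg, stats)
        b = train(graphs, ModelConfig(epochs=4, seed=1), emb, cfg, stats)
        assert a.history["loss"].tolist() == b.history["loss"].tolist()
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_no_positive_edges_is_training_error(self, toy_setup):
        graphs, emb, cfg, stats = toy_setup
        import copy

        g = copy.deepcopy(graphs[0])
        g.tc_label[:] = -1
        with pytest.raises(TrainingError, match="positive"):
            train([g], ModelConfig(epochs=1, seed=0), emb, cfg, stats)


class TestPrediction:
    def test_scores_in_unit_interval(self, toy_setup, tissue_small):
        graphs, emb, cfg, stats = toy_setup
        model = train(graphs, ModelConfig(epochs=4, seed=0), emb, cfg, stats)
        scores = model.predict_scores(graphs[0])
        assert len(scores) == len(graphs[0].tc_t)
        assert ((scores > 0) & (scores < 1)).all()

    def test_eval_mode_deterministic(self, toy_setup):
        graphs, emb, cfg, stats = toy_setup
        model = train(graphs, ModelConfig(epochs=4, seed=0), emb, cfg, stats)
        np.testing.assert_array_equal(
            model.predict_scores(graphs[0]), model.predict_scores(graphs[0])
        )

    def test_empty_edge_graph_gives_empty_scores(self, toy_setup):
        import copy

        graphs, emb, cfg, stats = toy_setup
        model = train(graphs, ModelConfig(epochs=2, seed=0), emb, cfg, stats)
        g = copy.deepcopy(graphs[0])
        g.tc_t = g.tc_t[:0]
        g.tc_c = g.tc_c[:0]
        g.tc_dist = g.tc_dist[:0]
        g.tc_pdist = g.tc_pdist[:0]
        g.tc_label = g.tc_label[:0]
        scores, latents = model.predict(g, refine_iters=0)
        assert scores.size == 0 and latents.shape[0] == g.n_transcripts

    def test_save_load_round_trip(self, toy_setup, tmp_path):
        graphs, emb, cfg, stats = toy_setup
        model = train(graphs, ModelConfig(epochs=2, seed=0), emb, cfg, stats)
        path = tmp_path / "model.npz"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_array_equal(
            model.predict_scores(graphs[0]), back.predict_scores(graphs[0])
        )
        assert back.config == model.config
        assert back.genes == model.genes


class TestEdgeGeometry:
    def test_margin_sign_and_symmetry(self, toy_setup):
        graphs, *_ = toy_setup
        g = graphs[0]
        geom = edge_geometry(g, max_dist=15.0)
        # each transcript's closest candidate has non-positive margin
        import pandas as pd

        df = pd.DataFrame({"t": g.tc_t, "pd": g.tc_pdist, "m": geom[:, 0]})
        closest = df.loc[df.groupby("t")["pd"].idxmin()]
        multi = df.groupby("t").size()
        closest = closest[closest["t"].map(multi) > 1]
        assert (closest["m"] <= 0).all()

    def test_coherence_in_unit_range(self, toy_setup):
        graphs, *_ = toy_setup
        geom = edge_geometry(graphs[0], max_dist=15.0)
        assert (np.abs(geom[:, 1]) <= 1 + 1e-12).all()
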