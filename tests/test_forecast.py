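"""Pyramid graph construction, attention masking, autodiff and training behavior."""

import numpy as np
import pandas as pd
import pytest

from wheatrisk.forecast.autodiff import Tensor
from wheatrisk.forecast.model import (
    PyramidAttentionModel,
    PyramidConfig,
    build_pyramid_graph,
    build_series,
    fit_forecaster,
    load_forecaster,
    make_windows,
    save_forecaster,
)

TINY = dict(window=8, children=2, scales=3, neighbor_radius=1, width=8, heads=2)


def tiny_config(**overrides):
    return PyramidConfig(**{**TINY, **overrides})


def reference_adjacency(t, c, s, a):
    """Independent set-based adjacency builder used as the oracle."""
    counts = [t]
    for _ in range(s - 1):
        counts.append(int(np.ceil(counts[-1] / c)))
    nodes = [(scale, i) for scale, count in enumerate(counts) for i in range(count)]
    index = {node: flat for flat, node in enumerate(nodes)}
    allowed = {node: set() for node in nodes}
    for scale, i in nodes:
        for j in range(counts[scale]):
            if abs(i - j) <= a:
                allowed[(scale, i)].add((scale, j))
        if scale + 1 < s:
            allowed[(scale, i)].add((scale + 1, i // c))
        if scale > 0:
            for j in range(counts[scale - 1]):
                if j // c == i:
                    allowed[(scale, i)].add((scale - 1, j))
    n = len(nodes)
    mask = np.zeros((n, n), dtype=bool)
    for q, keys in allowed.items():
        for k in keys:
            mask[index[q], index[k]] = True
    return counts, mask


class TestPyramidGraph:
    def test_node_counts_by_repeated_ceil_division(self):
        graph = build_pyramid_graph(tiny_config())
        assert graph.node_counts == (8, 4, 2)
        assert graph.total_nodes == 14

    def test_finest_corner_node_attends_self_neighbor_parent(self):
        graph = build_pyramid_graph(tiny_config())
        keys = set(np.flatnonzero(graph.mask[0]))
        assert keys == {0, 1, 8}

    def test_every_coarse_node_owns_c_children(self):
        graph = build_pyramid_graph(tiny_config())
        for i in range(4):  # scale-1 nodes sit at flat indices 8..11
            children = np.flatnonzero(graph.mask[8 + i, :8])
            assert len(children) == 2

    def test_interior_finest_node_has_at_most_four_keys(self):
        graph = build_pyramid_graph(tiny_config())
        assert graph.mask[3].sum() == 4  # self, two neighbors, parent

    @pytest.mark.parametrize(
        "t, c, s, a", [(8, 2, 3, 1), (24, 4, 3, 1), (12, 3, 2, 2), (27, 3, 4, 1)]
    )
    def test_matches_reference_adjacency(self, t, c, s, a):
        cfg = PyramidConfig(window=t, children=c, scales=s, neighbor_radius=a,
                            width=8, heads=2)
        graph = build_pyramid_graph(cfg)
        counts, mask = reference_adjacency(t, c, s, a)
        assert list(graph.node_counts) == counts
        np.testing.assert_array_equal(graph.mask, mask)

    def test_parent_child_symmetry(self):
        graph = build_pyramid_graph(tiny_config())
        offsets = graph.scale_offsets
        for scale in range(1, len(graph.node_counts)):
            for i in range(graph.node_counts[scale]):
                q = offsets[scale] + i
                children = np.flatnonzero(graph.mask[q, : offsets[1]] if scale == 1
                                          else graph.mask[q])
                for child in children:
                    if offsets[scale - 1] <= child < offsets[scale]:
                        assert graph.mask[child, q]

    def test_window_too_small_for_scales(self):
        with pytest.raises(ValueError, match="C"):
            PyramidConfig(window=3, children=2, scales=3, width=8, heads=2)


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        """Full forward pass gradient check on a tiny model."""
        cfg = tiny_config(seed=1)
        model = PyramidAttentionModel(cfg)
        rng = np.random.default_rng(0)
        values = rng.normal(size=(2, cfg.window))
        weeks = rng.integers(1, 53, size=(2, cfg.window))
        target = rng.normal(size=2)

        def loss_value():
            pred = model.forward(values, weeks)
            diff = pred - Tensor(target)
            return (diff * diff).mean()

        loss = loss_value()
        loss.backward()
        eps = 1e-6
        for p in [model.value_w, model.wq, model.ff1_w, model.head_w, model.cscm_w[0]]:
            grad = p.grad
            idx = (0, 0) if p.data.ndim == 2 else (0,)
            original = p.data[idx]
            p.data[idx] = original + eps
            up = float(loss_value().data)
            p.data[idx] = original - eps
            down = float(loss_value().data)
            p.data[idx] = original
            numeric = (up - down) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)

    def test_masked_softmax_singleton_key(self):
        scores = Tensor(np.array([[5.0, -2.0, 1.0]]))
        mask = np.array([[False, True, False]])
        weights = scores.masked_softmax(mask)
        np.testing.assert_array_equal(weights.data, [[0.0, 1.0, 0.0]])


class TestModelForward:
    def test_embedding_shape_and_covariate_sensitivity(self):
        cfg = tiny_config(seed=0)
        model = PyramidAttentionModel(cfg)
        values = np.zeros((1, cfg.window))
        weeks = np.full((1, cfg.window), 10)
        emb = model.embed_inputs(values, weeks)
        assert emb.data.shape == (1, cfg.window, cfg.width)
        other = model.embed_inputs(values, np.full((1, cfg.window), 11))
        assert not np.allclose(emb.data, other.data)

    def test_zeroed_embeddings_leave_positional_encoding(self):
        cfg = tiny_config(seed=0)
        model = PyramidAttentionModel(cfg)
        model.week_emb.data[:] = 0.0
        model.value_b.data[:] = 0.0
        emb = model.embed_inputs(np.zeros((1, cfg.window)), np.ones((1, cfg.window), int))
        np.testing.assert_allclose(emb.data[0], model.pe)

    def test_cscm_block_shapes_and_constant_symmetry(self):
        cfg = tiny_config(seed=0)
        model = PyramidAttentionModel(cfg)
        constant = Tensor(np.tile(np.arange(cfg.width, dtype=float), (1, cfg.window, 1)))
        features = model.cscm_forward(constant)
        assert [f.data.shape[1] for f in features] == [8, 4, 2]
        for block in features[1:]:
            np.testing.assert_allclose(
                block.data, np.broadcast_to(block.data[:, :1, :], block.data.shape)
            )

    def test_total_nodes_match_graph(self):
        for kwargs in (TINY, dict(window=24, children=4, scales=3, width=16, heads=4)):
            cfg = PyramidConfig(**{**kwargs, "neighbor_radius": 1})
            model = PyramidAttentionModel(cfg)
            emb = model.embed_inputs(
                np.zeros((2, cfg.window)), np.ones((2, cfg.window), int)
            )
            nodes = Tensor.concat(model.cscm_forward(emb), axis=1)
            assert nodes.data.shape[1] == model.graph.total_nodes

    def test_masked_positions_cannot_influence_any_query(self):
        """Perturbing a node outside a query's key set leaves that query's
        attention output bit-identical."""
        cfg = tiny_config(seed=2)
        model = PyramidAttentionModel(cfg)
        rng = np.random.default_rng(3)
        nodes = rng.normal(size=(1, model.graph.total_nodes, cfg.width))
        base = model.pam_forward(Tensor(nodes)).data
        mask = model.graph.mask
        query = 3
        hidden = int(np.flatnonzero(~mask[query])[0])
        perturbed = nodes.copy()
        perturbed[0, hidden, :] += 100.0
        out = model.pam_forward(Tensor(perturbed)).data
        np.testing.assert_array_equal(out[0, query], base[0, query])

    def test_attention_rows_sum_to_one_within_mask(self):
        cfg = tiny_config(seed=2)
        model = PyramidAttentionModel(cfg)
        rng = np.random.default_rng(4)
        n = model.graph.total_nodes
        x = Tensor(rng.normal(size=(1, n, cfg.width)))
        b, h, dh = 1, cfg.heads, cfg.width // cfg.heads
        q = (x @ model.wq).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        k = (x @ model.wk).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        weights = scores.masked_softmax(model.graph.mask).data
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0)
        forbidden = ~model.graph.mask
        assert (weights[0][:, forbidden] == 0.0).all()


class TestTraining:
    def test_loss_trace_finite_and_decreasing_overall(self, rng):
        series = np.sin(np.arange(60) / 5.0) + 0.05 * rng.normal(size=60)
        weeks = (np.arange(60) % 52) + 1
        model = fit_forecaster(series, weeks, tiny_config(epochs=30, seed=5))
        trace = np.asarray(model.loss_trace)
        assert np.isfinite(trace).all()
        assert trace[-1] <= trace[0]

    def test_fixed_seed_reproducible(self, rng):
        series = rng.normal(size=40)
        weeks = (np.arange(40) % 52) + 1
        cfg = tiny_config(epochs=10, seed=8)
        a = fit_forecaster(series, weeks, cfg)
        b = fit_forecaster(series, weeks, cfg)
        window, wk = series[-8:], weeks[-8:]
        assert a.predict_next(window, wk) == b.predict_next(window, wk)
        for pa, pb in zip(a.model.parameters, b.model.parameters):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_constant_series_predicted_within_five_percent(self):
        # length > 52 + T so every week-of-year embedding row the inference
        # window uses was also seen during training
        series = np.full(64, 3.0)
        weeks = (np.arange(64) % 52) + 1
        model = fit_forecaster(series, weeks, tiny_config(epochs=50, seed=6))
        pred = model.predict_next(series[-8:], weeks[-8:])
        assert pred == pytest.approx(3.0, rel=0.05)

    def test_ar1_one_step_rmse_close_to_noise_floor(self):
        """On an AR(1) series (phi=0.8) the optimal one-step RMSE is sigma;
        the model should come within 50% of that floor."""
        rng = np.random.default_rng(99)
        sigma, phi, n = 0.1, 0.8, 220
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + sigma * rng.normal()
        weeks = (np.arange(n) % 52) + 1
        split = 170
        model = fit_forecaster(x[:split], weeks[:split], tiny_config(epochs=60, seed=7))
        preds = [
            model.predict_next(x[t - 8 : t], weeks[t - 8 : t]) for t in range(split, n)
        ]
        rmse = float(np.sqrt(np.mean((np.asarray(preds) - x[split:]) ** 2)))
        assert rmse <= 1.5 * sigma

    def test_wrong_window_length_rejected(self, rng):
        series = rng.normal(size=40)
        weeks = (np.arange(40) % 52) + 1
        model = fit_forecaster(series, weeks, tiny_config(epochs=2, seed=1))
        with pytest.raises(ValueError, match="window"):
            model.predict_next(series[:5], weeks[:5])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fit_forecaster(np.zeros(8), np.ones(8, int), tiny_config())

    def test_checkpoint_round_trip(self, rng, tmp_path):
        series = rng.normal(size=40)
        weeks = (np.arange(40) % 52) + 1
        model = fit_forecaster(series, weeks, tiny_config(epochs=5, seed=2))
        save_forecaster(model, tmp_path, "s1")
        loaded = load_forecaster(tmp_path, "s1")
        assert loaded.predict_next(series[-8:], weeks[-8:]) == model.predict_next(
            series[-8:], weeks[-8:]
        )


class TestBuildSeries:
    def frame(self, weeks):
        return pd.DataFrame(
            {
                "province": "P01",
                "week": weeks,
                "nipi": np.linspace(0, 1, len(weeks)),
                "thq": np.linspace(1, 2, len(weeks)),
                "tcr": np.linspace(0, 1e-5, len(weeks)),
            }
        )

    def test_full_length_and_week_wrap(self):
        series, weeks = build_series(self.frame(range(1, 160)), "P01", "nipi")
        assert len(series) == 159
        assert weeks[52] == 1  # global week 53 wraps to week-of-year 1
        assert weeks[0] == 1 and weeks[51] == 52

    def test_gap_listed_in_error(self):
        frame = self.frame([1, 2, 4, 5])
        with pytest.raises(ValueError, match=r"\[3\]"):
            build_series(frame, "P01", "nipi")

    def test_unknown_province_or_indicator(self):
        frame = self.frame([1, 2, 3])
        with pytest.raises(ValueError, match="P09"):
            build_series(frame, "P09", "nipi")
        with pytest.raises(ValueError, match="bogus"):
            build_series(frame, "P01", "bogus")

    def test_windowing_arity(self):
        series = np.arange(30.0)
        weeks = (np.arange(30) % 52) + 1
        values, wk, targets = make_windows(series, weeks, 8)
        assert values.shape == (22, 8) and targets.shape == (22,)
        np.testing.assert_array_equal(values[0], series[:8])
        assert targets[0] == series[8]
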