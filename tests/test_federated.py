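"""Server-side aggregation and communication rounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfmgl.data import ArrayDataset
from vfmgl.ddbl_kd import Stage2Config
from vfmgl.federated import (ClientState, SharedState, aggregate,
                             frozen_param_prefixes, run_round)
from vfmgl.model_zoo import build_model


def toy_params(rng, n=3):
    return [{"w": rng.normal(size=(4, 5)), "b": rng.normal(size=5)}
            for _ in range(n)]


class TestAggregate:
    def test_identical_clients_any_weights(self, rng):
        p = toy_params(rng, 1)[0]
        out = aggregate([p, {k: v.copy() for k, v in p.items()}], [0.9, 3.1])
        for k in p:
            np.testing.assert_allclose(out.params[k], p[k])

    def test_two_scalar_average(self):
        out = aggregate([{"x": np.array(1.0)}, {"x": np.array(3.0)}],
                        [0.5, 0.5])
        assert out.params["x"] == pytest.approx(2.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        params = toy_params(rng, 3)
        weights = np.array([10.0, 20.0, 30.0])
        out = aggregate(params, weights)
        wn = weights / weights.sum()
        for k in params[0]:
            expect = np.zeros_like(params[0][k])
            for it in np.ndindex(*params[0][k].shape):
                expect[it] = sum(wn[i] * params[i][k][it] for i in range(3))
            np.testing.assert_allclose(out.params[k], expect, atol=1e-15)

    def test_permutation_invariance(self, rng):
        params = toy_params(rng, 3)
        w = [1.0, 2.0, 3.0]
        a = aggregate(params, w)
        b = aggregate([params[2], params[0], params[1]], [3.0, 1.0, 2.0])
        for k in a.params:
            np.testing.assert_allclose(a.params[k], b.params[k])

    def test_homogeneous_degree_one(self, rng):
        params = toy_params(rng, 2)
        w = [1.0, 4.0]
        scaled = [{k: 2.5 * v for k, v in p.items()} for p in params]
        a = aggregate(params, w)
        b = aggregate(scaled, w)
        for k in a.params:
            np.testing.assert_allclose(b.params[k], 2.5 * a.params[k])

    def test_convexity_elementwise(self, rng):
        params = toy_params(rng, 3)
        out = aggregate(params, [1.0, 1.0, 2.0])
        for k in params[0]:
            stack = np.stack([p[k] for p in params])
            assert np.all(out.params[k] >= stack.min(axis=0) - 1e-12)
            assert np.all(out.params[k] <= stack.max(axis=0) + 1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=5),
           st.integers(0, 2 ** 31 - 1))
    def test_convexity_and_normalization_for_arbitrary_weights(
            self, weights, data_seed):
        """Every aggregated element is a convex combination of the client
        values, whatever the (positive) weight vector."""
        gen = np.random.default_rng(data_seed)
        params = [{"w": gen.normal(size=(3, 3))} for _ in weights]
        out = aggregate(params, weights)
        stack = np.stack([p["w"] for p in params])
        assert np.all(out.params["w"] >= stack.min(axis=0) - 1e-9)
        assert np.all(out.params["w"] <= stack.max(axis=0) + 1e-9)
        equal = aggregate(params, [1.0] * len(weights))
        np.testing.assert_allclose(equal.params["w"], stack.mean(axis=0))

    def test_errors(self, rng):
        params = toy_params(rng, 2)
        with pytest.raises(ValueError, match="at least one"):
            aggregate([], [])
        with pytest.raises(ValueError, match="not all zero"):
            aggregate(params, [0.0, 0.0])
        bad = [params[0], {"w": np.zeros((2, 2)), "b": np.zeros(5)}]
        with pytest.raises(ValueError, match="shape mismatch"):
            aggregate(bad, [1.0, 1.0])


class TestRunRound:
    def _client(self, spec, rng, seed, frozen=(), n=16):
        model = build_model(spec, seed=seed)
        data = ArrayDataset(rng.random((n, 3, 32, 32)),
                            rng.integers(0, 2, n))
        cfg = Stage2Config(batch_size=8, epochs=1, lr=0.02,
                           keep_fraction=1.0, seed=seed)
        return ClientState(center_id=f"c{seed}", model=model,
                           train_data=data, frozen_layers=tuple(frozen),
                           config=cfg)

    def test_single_client_round_returns_its_params(
            self, tiny_student_spec, rng):
        client = self._client(tiny_student_spec, rng, 0)
        shared = SharedState(client.model.state_dict())
        factory = lambda: build_model(tiny_student_spec, seed=9)
        (client,), shared2 = run_round([client], shared, factory)
        for k, v in client.model.state_dict().items():
            np.testing.assert_array_equal(shared2.params[k], v)
        assert shared2.round_index == 1

    def test_identical_clients_stay_identical(self, tiny_student_spec, rng):
        seed_data = np.random.default_rng(7)
        imgs = seed_data.random((16, 3, 32, 32))
        labels = seed_data.integers(0, 2, 16)
        clients = []
        for _ in range(2):
            m = build_model(tiny_student_spec, seed=4)
            clients.append(ClientState(
                center_id="twin", model=m,
                train_data=ArrayDataset(imgs.copy(), labels.copy()),
                config=Stage2Config(batch_size=8, epochs=1,
                                    keep_fraction=1.0, seed=4)))
        shared = SharedState(clients[0].model.state_dict())
        factory = lambda: build_model(tiny_student_spec, seed=4)
        clients, _ = run_round(clients, shared, factory)
        a = clients[0].model.state_dict()
        b = clients[1].model.state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_frozen_layers_survive_rounds_bit_identical(
            self, tiny_student_spec, rng):
        client = self._client(tiny_student_spec, rng, 1,
                              frozen=["stage1", "stage2"])
        other = self._client(tiny_student_spec, rng, 2)
        checksums = {n: p.data.tobytes()
                     for n, p in client.model.named_parameters()
                     if n.startswith(("layer1.", "layer2."))}
        shared = SharedState(aggregate(
            [client.model.state_dict(), other.model.state_dict()],
            [1, 1]).params)
        factory = lambda: build_model(tiny_student_spec, seed=9)
        for _ in range(2):
            (client, other), shared = run_round([client, other], shared,
                                                factory)
        for n, p in client.model.named_parameters():
            if n in checksums:
                assert p.data.tobytes() == checksums[n]

    def test_message_log_contains_no_image_shaped_tensors(
            self, tiny_student_spec, rng):
        client = self._client(tiny_student_spec, rng, 3)
        shared = SharedState(client.model.state_dict())
        factory = lambda: build_model(tiny_student_spec, seed=9)
        log = []
        run_round([client], shared, factory, log=log)
        img_shape = client.train_data.images.shape[1:]
        for entry in log:
            for shape in entry["shapes"].values():
                assert shape[-3:] != img_shape

    def test_client_failure_surfaces_center_id(self, tiny_student_spec, rng):
        client = self._client(tiny_student_spec, rng, 5)
        client.config = Stage2Config(batch_size=8, keep_fraction=0.01)
        shared = SharedState(client.model.state_dict())
        factory = lambda: build_model(tiny_student_spec, seed=9)
        with pytest.raises(RuntimeError, match="c5"):
            run_round([client], shared, factory)

    def test_frozen_prefix_translation(self, tiny_student_spec):
        model = build_model(tiny_student_spec, seed=0)
        prefixes = frozen_param_prefixes(model, ["stage2", "stage4"])
        assert prefixes == frozenset({"layer2", "layer4"})
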