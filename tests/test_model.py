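"""Network modules: encoders, fusion, heads, feature encoding, serialization."""

import numpy as np
import pytest

from hibpn import model as M
from hibpn.cohort import CohortConfig, generate_cohort
from hibpn.training import TrainConfig, split_1_9, train_hibpn


def _zero_params(dims: M.HibpnDims) -> M.HibpnParams:
    p = M.init_params(dims, 0)
    for layer in p.layers().values():
        layer.weights[:] = 0.0
        layer.bias[:] = 0.0
    return p


@pytest.fixture()
def tiny_dims():
    return M.HibpnDims(he_in=2, he_up=4, he_down=2, narc_in=2, narc_up=3,
                       hostile_in=2, hostile_mid=2, env_hidden=3, hostile_hidden=3)


class TestInit:
    def test_determinism(self, tiny_dims):
        a, b = M.init_params(tiny_dims, 5), M.init_params(tiny_dims, 5)
        for (na, la), (nb, lb) in zip(a.layers().items(), b.layers().items()):
            assert na == nb
            np.testing.assert_array_equal(la.weights, lb.weights)

    def test_upscale_downscale_constraints(self):
        M.HibpnDims(he_in=8, he_up=32, he_down=8).validate()  # fine
        with pytest.raises(ValueError):
            M.HibpnDims(he_in=8, he_up=8).validate()  # no upscaling
        with pytest.raises(ValueError):
            M.HibpnDims(he_in=4, he_up=8, he_down=8).validate()  # no downscaling
        with pytest.raises(ValueError):
            M.HibpnDims(narc_in=4, narc_up=3).validate()


class TestEncoders:
    def test_zero_params_give_zero_vectors(self, tiny_dims):
        p = _zero_params(tiny_dims)
        x = np.array([[1.0, -2.0]])
        assert np.all(M.human_env_encode(x, p) == 0)
        assert np.all(M.narcissism_encode(x, p) == 0)
        assert np.all(M.hostile_intermediate(x, p) == 0)

    def test_identity_like_layers_pass_positive_input(self):
        dims = M.HibpnDims(he_in=1, he_up=2, he_down=1, narc_in=1, narc_up=2,
                           hostile_in=1, hostile_mid=1, env_hidden=2, hostile_hidden=2)
        p = _zero_params(dims)
        p.he_up.weights[:] = [[1.0], [0.0]]
        p.he_down.weights[:] = [[1.0, 0.0]]
        out = M.human_env_encode(np.array([[2.0]]), p)
        assert out[0, 0] == pytest.approx(2.0)

    def test_narcissism_linear_case(self, tiny_dims):
        p = _zero_params(tiny_dims)
        p.narc_up.weights[0] = [1.0, 1.0]
        out = M.narcissism_encode(np.array([[16.0, 50.0]]), p)
        assert out[0, 0] == pytest.approx(66.0)
        # negative pre-activation clips to zero under ReLU
        p.narc_up.weights[0] = [-1.0, 0.0]
        assert M.narcissism_encode(np.array([[16.0, 50.0]]), p)[0, 0] == 0.0

    def test_hostile_intermediate_linear_case(self, tiny_dims):
        p = _zero_params(tiny_dims)
        p.hostile_mid.weights[0] = [1.0, -1.0]
        out = M.hostile_intermediate(np.array([[40.0, 30.0]]), p)
        assert out[0, 0] == pytest.approx(10.0)

    def test_dimension_mismatch_rejected(self, tiny_dims):
        p = M.init_params(tiny_dims, 0)
        with pytest.raises(ValueError):
            M.human_env_encode(np.ones((1, 5)), p)


class TestFusion:
    def test_concatenation_length_and_order(self):
        out = M.fuse(np.ones((1, 3)), 2 * np.ones((1, 2)))
        assert out.shape == (1, 5)
        np.testing.assert_array_equal(out[0], [1, 1, 1, 2, 2])

    def test_empty_narcissism_block_is_identity(self):
        a = np.ones((4, 3))
        np.testing.assert_array_equal(M.fuse(a, np.zeros((4, 0))), a)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            M.fuse(np.array([[np.nan]]), np.array([[1.0]]))


class TestHeads:
    def test_zero_output_layer_gives_half(self, tiny_dims):
        p = _zero_params(tiny_dims)
        a_hen = np.ones((1, tiny_dims.fused_dim))
        a_mid = np.ones((1, tiny_dims.hostile_mid))
        assert M.forward_chain(a_hen, a_mid, p)[0] == pytest.approx(0.5)

    def test_large_bias_saturates_towards_one(self, tiny_dims):
        p = _zero_params(tiny_dims)
        p.env_out.bias[:] = 50.0
        a_hen = np.zeros((1, tiny_dims.fused_dim))
        a_mid = np.zeros((1, tiny_dims.hostile_mid))
        assert M.forward_chain(a_hen, a_mid, p)[0] > 1 - 1e-9

    def test_probabilities_bounded(self, tiny_dims):
        p = M.init_params(tiny_dims, 3)
        rng = np.random.default_rng(0)
        a_hen = rng.normal(size=(20, tiny_dims.fused_dim))
        a_mid = rng.normal(size=(20, tiny_dims.hostile_mid))
        pf = M.forward_chain(a_hen, a_mid, p)
        assert np.all((pf > 0) & (pf < 1))
        y_cont, p_high = M.reverse_chain(a_hen, p)
        assert np.all((p_high > 0) & (p_high < 1))

    def test_reverse_zero_params_zero_regression(self, tiny_dims):
        p = _zero_params(tiny_dims)
        y_cont, p_high = M.reverse_chain(np.ones((1, tiny_dims.fused_dim)), p)
        assert y_cont[0] == 0.0 and p_high[0] == pytest.approx(0.5)

    def test_pure_functions_deterministic(self, tiny_dims):
        p = M.init_params(tiny_dims, 3)
        a = np.random.default_rng(1).normal(size=(5, tiny_dims.fused_dim))
        np.testing.assert_array_equal(M.reverse_chain(a, p)[0], M.reverse_chain(a, p)[0])


class TestFeatureEncoding:
    def test_condition_excluded_from_forward_inputs(self, small_cohort):
        fm = M.build_features(small_cohort, "forward")
        assert "condition_exclusion" not in fm.he_columns
        assert "condition_exclusion" in M.build_features(small_cohort, "reverse").he_columns

    def test_forward_predictions_invariant_to_condition_permutation(self, small_cohort):
        """Anti-leakage: the target column cannot influence forward predictions."""
        from hibpn.cohort import shuffle_conditions

        cfg = TrainConfig(epochs=100, seed=0)
        train, test = split_1_9(small_cohort, cfg)
        model = train_hibpn(train, cfg)
        permuted = shuffle_conditions(test, seed=3)
        np.testing.assert_array_equal(
            model.predict_forward(test), model.predict_forward(permuted)
        )

    def test_every_column_mapped_to_one_group(self, small_cohort):
        for chain in ("forward", "reverse"):
            fm = M.build_features(small_cohort, chain)
            _, cols = fm.flat()
            assert set(cols) == set(fm.dimension_group_map)

    def test_drop_groups_removes_exact_columns(self, small_cohort):
        fm = M.build_features(small_cohort, "forward", drop_groups=["narcissism"])
        _, cols = fm.flat()
        assert all(M.DIMENSION_GROUPS[c] != "narcissism" for c in cols)
        with pytest.raises(ValueError):
            M.build_features(small_cohort, "forward", drop_groups=["nonexistent"])


class TestLogisticEquivalence:
    def test_network_matches_logistic_regression_on_separable_data(self):
        """On linearly separable data both the network and a reference
        logistic fit recover the same decision rule."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(11)
        x = rng.normal(size=(40, 2))
        y = (x[:, 0] + x[:, 1] > 0).astype(float)
        x[y == 1] += 0.8
        x[y == 0] -= 0.8

        ref = LogisticRegression(C=1e6).fit(x, y)
        from hibpn.model import HibpnDims
        from hibpn.training import train_chain

        fm = M.FeatureMatrix(
            he=x, narc=np.zeros((40, 0)), hostile=np.zeros((40, 0)),
            he_columns=("f1", "f2"), narc_columns=(), hostile_columns=(),
            y_forward=y, y_reverse=y, y_reverse_cont=y, chain="forward",
            dimension_group_map={"f1": "social_exclusion", "f2": "social_exclusion"},
        )
        dims = HibpnDims(he_in=2, he_up=8, he_down=4, narc_in=0, narc_up=0,
                         hostile_in=0, hostile_mid=0, env_hidden=4, hostile_hidden=4)
        cm = train_chain(fm, TrainConfig(epochs=2000, learning_rate=0.5, seed=1), dims=dims)
        np.testing.assert_array_equal(cm.predict_labels(fm), ref.predict(x).astype(int))


def test_params_roundtrip_bit_exact(tmp_path, tiny_dims):
    p = M.init_params(tiny_dims, 7)
    path = tmp_path / "params.npz"
    M.save_params(p, str(path))
    q = M.load_params(str(path))
    assert vars(q.dims) == vars(tiny_dims)
    for name, layer in p.layers().items():
        np.testing.assert_array_equal(layer.weights, q.layers()[name].weights)
        np.testing.assert_array_equal(layer.bias, q.layers()[name].bias)
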