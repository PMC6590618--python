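"""Length estimators, coefficient models, and the sklearn-style regressor."""

import json
import warnings

import numpy as np
import pytest
from sklearn.base import clone

from sncontour.chaincode import ChainCode, reverse_chain_code
from sncontour.length import (
    REFERENCE_COEFFICIENT_MODEL,
    SEGMENT_LENGTHS,
    SQRT2,
    ExtrapolationWarning,
    LinearCoefficientModel,
    ShapeLengthModel,
    coefficients_at,
    corner_length,
    dna_length,
    freeman_length,
    kulpa_length,
    shape_length,
)
from sncontour.shapes import ShapeTally, tally, tally_matrix  # noqa: F401

EXAMPLE = ChainCode.from_string("07107565")  # n_e=3, n_o=5


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (freeman_length, (3, 0, 1.0), 3.0),
        (freeman_length, (0, 2, 2.0), 4 * SQRT2),
        (freeman_length, (3, 5, 1.0), 3 + 5 * SQRT2),
        (kulpa_length, (1, 0, 1.0), 0.948),
        (kulpa_length, (0, 1, 1.0), 1.343),
        (kulpa_length, (10, 10, 2.0), 45.82),
        (corner_length, (1, 0, 0, 1.0), 0.980),
        (corner_length, (0, 1, 0, 1.0), 1.406),
        (corner_length, (2, 2, 3, 1.0), 4.499),
    ],
)
def test_baseline_estimator_values(fn, args, expected):
    assert fn(*args) == pytest.approx(expected)


def test_example_chain_counts_feed_freeman():
    assert freeman_length(EXAMPLE.n_even, EXAMPLE.n_odd, 1.0) == pytest.approx(
        3 + 5 * SQRT2)


def test_dna_length_scales_freeman():
    assert dna_length(2, 0, 1.0, 1.0) == pytest.approx(2.0)
    assert dna_length(2, 0, 1.0, 0.5) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        dna_length(1, 1, 1.0, -0.1)


class TestShapeLength:
    def test_unit_coefficients_reduce_to_freeman(self, chain_factory):
        rng = np.random.default_rng(2)
        ones = np.ones(12)
        for _ in range(50):
            cc = chain_factory(rng, int(rng.integers(3, 50)))
            assert shape_length(cc, ones, 3.7) == pytest.approx(
                freeman_length(cc.n_even, cc.n_odd, 3.7), rel=1e-12)

    def test_straight_chain_arithmetic(self):
        k = np.ones(12)
        k[0] = 1.01
        assert shape_length(ChainCode.from_string("0000"), k, 2.0) == \
            pytest.approx(2.0 * (2 * 1.01 + 1 + 1))

    def test_head_tail_only(self):
        t = ShapeTally(np.zeros(12, dtype=int), head_code=0, tail_code=2)
        assert shape_length(t, np.ones(12), 1.0) == pytest.approx(2.0)

    def test_traversal_direction_invariance(self, chain_factory):
        rng = np.random.default_rng(3)
        k = rng.uniform(0.6, 1.2, size=12)
        for _ in range(10):
            cc = chain_factory(rng, 30)
            assert shape_length(cc, k, 5.1) == pytest.approx(
                shape_length(reverse_chain_code(cc), k, 5.1))

    def test_linear_in_resolution(self, chain_factory):
        cc = random = np.random.default_rng(4)
        cc = chain_factory(random, 25)
        k = np.full(12, 0.9)
        assert shape_length(cc, k, 10.2) == pytest.approx(
            2 * shape_length(cc, k, 5.1))

    def test_requires_twelve_coefficients(self):
        with pytest.raises(ValueError):
            shape_length(ChainCode.from_string("0000"), np.ones(5), 1.0)


class TestCoefficientsAt:
    def test_reference_model_values(self):
        k = coefficients_at(6.4, REFERENCE_COEFFICIENT_MODEL)
        assert k[9] == pytest.approx(0.92647, abs=5e-6)   # k10 line
        k = coefficients_at(5.1, REFERENCE_COEFFICIENT_MODEL)
        assert k[0] == pytest.approx(1.02526, abs=5e-6)   # k1 line

    def test_flat_model_gives_unit_coefficients(self):
        model = LinearCoefficientModel.from_lines(np.zeros(12), np.ones(12))
        assert np.allclose(model.coefficients_at(6.0), 1.0)

    def test_extrapolation_warns(self):
        with pytest.warns(ExtrapolationWarning):
            REFERENCE_COEFFICIENT_MODEL.coefficients_at(9.0)

    def test_json_roundtrip(self, tmp_path):
        f = tmp_path / "coeffs.json"
        REFERENCE_COEFFICIENT_MODEL.to_json(f)
        back = LinearCoefficientModel.from_json(f)
        assert np.allclose(back.slope_, REFERENCE_COEFFICIENT_MODEL.slope_)
        assert np.allclose(back.intercept_,
                           REFERENCE_COEFFICIENT_MODEL.intercept_)
        obj = json.loads(f.read_text())
        assert obj["k10"]["m"] == pytest.approx(0.032808)


class TestShapeLengthModel:
    def _chains(self, rng, n, chain_factory):
        return [chain_factory(rng, int(rng.integers(10, 60)))
                for _ in range(n)]

    def test_recovers_known_coefficients(self, chain_factory):
        rng = np.random.default_rng(7)
        chains = self._chains(rng, 80, chain_factory)
        X = tally_matrix(chains)
        k_true = rng.uniform(0.7, 1.2, size=12)
        r = 5.5
        y = r * (X[:, :12] @ (k_true * SEGMENT_LENGTHS) + X[:, 12] + X[:, 13])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rare classes may be absent
            model = ShapeLengthModel(resolution=r).fit(X, y)
        observed = [j for j in range(12) if j not in model.unobserved_]
        assert np.allclose(model.coef_[observed], k_true[observed],
                           rtol=1e-9)
        assert np.allclose(model.predict(X), y, rtol=1e-9)

    def test_accepts_chain_codes_directly(self, chain_factory):
        rng = np.random.default_rng(8)
        chains = self._chains(rng, 40, chain_factory)
        y = np.array([freeman_length(c.n_even, c.n_odd, 2.0) for c in chains])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ShapeLengthModel(resolution=2.0).fit(chains, y)
        assert np.allclose(model.predict(chains), y, rtol=1e-8)
        assert np.allclose(model.coef_, 1.0, atol=1e-8)

    def test_unobserved_classes_pinned_with_warning(self):
        chains = [ChainCode.from_string("0" * 10)] * 15
        y = np.full(15, 9.0 + 2.0)  # 9 unit steps + head/tail... true lengths
        with pytest.warns(UserWarning, match="never observed"):
            model = ShapeLengthModel(resolution=1.0).fit(chains, y)
        assert model.coef_[1:].tolist() == [1.0] * 11
        assert model.coef_[0] == pytest.approx(9.0 / 8.0)

    def test_sklearn_protocol(self):
        model = ShapeLengthModel(resolution=5.1)
        assert model.get_params()["resolution"] == 5.1
        cloned = clone(model).set_params(resolution=6.4)
        assert cloned.get_params()["resolution"] == 6.4

    def test_fixed_coefficients_predict_without_fit(self):
        model = ShapeLengthModel(resolution=1.0, coefficients=np.ones(12))
        cc = ChainCode.from_string("0000")
        assert model.predict([cc])[0] == pytest.approx(4.0)
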