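"""Coefficient calibration: system assembly, solving, lines, C_f, errors."""

import numpy as np
import pandas as pd
import pytest

from sncontour.calibrate import (
    assemble_system,
    convergence_curve,
    estimate_cf,
    evaluate,
    fit_coefficient_lines,
    solve_coefficients,
)
from sncontour.chaincode import ChainCode
from sncontour.length import SEGMENT_LENGTHS, SQRT2, freeman_length
from sncontour.shapes import tally_matrix


def _corpus(rng, chain_factory, n=60):
    return [chain_factory(rng, int(rng.integers(10, 60))) for _ in range(n)]


class TestAssembleSystem:
    def test_straight_chain_row(self):
        samples = [(ChainCode.from_string("0000"), 20.0)] * 12
        sys = assemble_system(samples, r=5.0)
        assert np.array_equal(sys.N[0], [2] + [0] * 11)
        assert sys.B[0] == pytest.approx(5.0 * 2)
        assert sys.L[0] == 20.0
        assert sys.unobserved == list(range(1, 12))

    def test_requires_twelve_samples(self):
        with pytest.raises(ValueError):
            assemble_system([(ChainCode.from_string("0000"), 5.0)] * 11, 1.0)

    def test_row_sums_match_interior_windows(self, chain_factory):
        rng = np.random.default_rng(9)
        chains = _corpus(rng, chain_factory, 20)
        sys = assemble_system([(c, 100.0) for c in chains], 2.0)
        assert np.array_equal(sys.N.sum(axis=1),
                              [len(c) - 2 for c in chains])

    def test_diagonal_matrix_constants(self, chain_factory):
        rng = np.random.default_rng(10)
        sys = assemble_system(
            [(c, 50.0) for c in _corpus(rng, chain_factory, 12)], 1.0)
        assert np.allclose(np.diag(sys.D), SEGMENT_LENGTHS)
        assert np.allclose(
            np.diag(sys.D),
            [1, SQRT2, 1, SQRT2, SQRT2, 1, SQRT2, SQRT2, SQRT2, 1, SQRT2,
             SQRT2])


class TestSolveCoefficients:
    def test_exact_recovery_on_consistent_system(self, chain_factory):
        rng = np.random.default_rng(12)
        chains = _corpus(rng, chain_factory, 100)
        X = tally_matrix(chains)
        k_true = rng.uniform(0.6, 1.3, size=12)
        r = 6.4
        L = r * (X[:, :12] @ (k_true * SEGMENT_LENGTHS) + X[:, 12] + X[:, 13])
        sol = solve_coefficients(
            assemble_system(list(zip(chains, L)), r))
        observed = [j for j in range(12) if j not in sol.unobserved]
        rel = np.abs(sol.k[observed] - k_true[observed]) / k_true[observed]
        assert rel.max() <= 1e-9

    def test_noisy_recovery_within_standard_errors(self, chain_factory):
        rng = np.random.default_rng(13)
        chains = _corpus(rng, chain_factory, 400)
        X = tally_matrix(chains)
        k_true = np.full(12, 1.0)
        r = 5.1
        L = r * (X[:, :12] @ (k_true * SEGMENT_LENGTHS) + X[:, 12] + X[:, 13])
        L = L + rng.normal(0, 2.0, size=len(L))
        sol = solve_coefficients(assemble_system(list(zip(chains, L)), r))
        observed = [j for j in range(12) if j not in sol.unobserved]
        z = (sol.k[observed] - 1.0) / sol.stderr[observed]
        assert np.abs(z).max() < 5.0

    def test_unit_coefficients_make_shape_equal_freeman(self, chain_factory):
        # when the generating truth is Freeman, the solve finds k = 1
        rng = np.random.default_rng(14)
        chains = _corpus(rng, chain_factory, 150)
        L = np.array([freeman_length(c.n_even, c.n_odd, 3.0) for c in chains])
        sol = solve_coefficients(assemble_system(list(zip(chains, L)), 3.0))
        observed = [j for j in range(12) if j not in sol.unobserved]
        assert np.allclose(sol.k[observed], 1.0, atol=1e-8)


class TestCoefficientLines:
    def test_two_points_interpolated_exactly(self):
        K1, K2 = np.full(12, 0.8), np.full(12, 1.0)
        model = fit_coefficient_lines([(5.0, K1), (7.0, K2)])
        assert np.allclose(model.coefficients_at(5.0), K1)
        assert np.allclose(model.coefficients_at(7.0), K2)
        assert np.allclose(model.slope_, 0.1)

    def test_recovers_reference_k5_line(self):
        m, b = -0.00027806, 0.7044
        rs = np.arange(5.1, 7.9, 0.1)
        K = np.tile(np.ones(12), (len(rs), 1))
        K[:, 4] = m * rs + b
        model = fit_coefficient_lines(list(zip(rs, K)))
        assert model.slope_[4] == pytest.approx(m, rel=1e-9)
        assert model.intercept_[4] == pytest.approx(b, rel=1e-9)
        assert model.r_squared_[4] == pytest.approx(1.0)

    def test_constant_coefficients_give_zero_slope(self):
        K = np.full(12, 0.95)
        model = fit_coefficient_lines([(5.1, K), (6.0, K), (7.8, K)])
        assert np.allclose(model.slope_, 0.0, atol=1e-12)


class TestConvergence:
    def test_duplicated_sample_set_gives_identical_coefficients(
            self, chain_factory):
        rng = np.random.default_rng(15)
        chains = _corpus(rng, chain_factory, 50)
        X = tally_matrix(chains)
        L = 2.0 * (X[:, :12] @ SEGMENT_LENGTHS + X[:, 12] + X[:, 13])
        X2, L2 = np.vstack([X, X]), np.concatenate([L, L])
        df = convergence_curve(X2, L2, [50, 100], r=2.0)
        k_cols = [f"k{j}" for j in range(1, 13)]
        assert np.allclose(df.loc[0, k_cols], df.loc[1, k_cols])
        assert df.loc[1, "max_rel_change"] == pytest.approx(0.0, abs=1e-12)

    def test_checkpoint_bounds_enforced(self):
        with pytest.raises(ValueError):
            convergence_curve(np.ones((20, 14)), np.ones(20), [5, 10], 1.0)


class TestEstimateCf:
    def test_exact_freeman_gives_unit_factor(self):
        cc = ChainCode.from_string("0000")
        lf = freeman_length(4, 0, 2.0)
        assert estimate_cf([(cc, lf)] * 10, 2.0) == pytest.approx(1.0)

    def test_three_percent_bias_compensated(self):
        cc = ChainCode.from_string("0000")
        lf = freeman_length(4, 0, 2.0)
        assert estimate_cf([(cc, lf / 1.03)] * 10, 2.0) == pytest.approx(
            0.97087, abs=1e-5)

    def test_mixed_lengths_rejected(self):
        cc = ChainCode.from_string("0000")
        with pytest.raises(ValueError):
            estimate_cf([(cc, 5.0), (cc, 6.0)], 1.0)


class TestEvaluate:
    def test_perfect_estimator_has_zero_error(self, chain_factory):
        rng = np.random.default_rng(16)
        chains = _corpus(rng, chain_factory, 30)
        df = evaluate(
            {"oracle": lambda cc: 123.0},
            [(123.0, 5.1, chains)],
        )
        row = df.iloc[0]
        assert row["relative_pct"] == 0.0
        assert row["absolute_nm"] == 0.0
        assert row["std_nm"] == 0.0
        assert row["n"] == 30

    def test_table_layout(self, chain_factory):
        rng = np.random.default_rng(17)
        chains = _corpus(rng, chain_factory, 10)
        df = evaluate(
            {"L_F": lambda cc: freeman_length(cc.n_even, cc.n_odd, 5.1)},
            [(340.0, 5.1, chains), (680.0, 5.1, chains)],
        )
        assert list(df.columns) == [
            "estimator", "lc_nm", "r_nm_per_px", "relative_pct",
            "absolute_nm", "std_nm", "n"]
        assert len(df) == 2
        assert isinstance(df, pd.DataFrame)
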