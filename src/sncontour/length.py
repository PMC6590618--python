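"""Contour-length estimators for chain-coded backbones.

Baselines, all in nm for a chain with ``n_e`` direct and ``n_o`` diagonal
connections at resolution ``r`` (nm/pixel):

    L_F   = r (n_e + sqrt(2) n_o)                       Freeman
    L_K   = r (0.948 n_e + 1.343 n_o)                   Kulpa
    L_C   = r (0.980 n_e + 1.406 n_o - 0.091 n_c)       corner-corrected
    L_DNA = r C_f (n_e + sqrt(2) n_o)                   factor-corrected

and the shape estimator

    L_S = r ( sum_j n_kj k_j l_kj + l_H + l_T )

which weights each interior connection by the correction coefficient k_j
of its 4-pixel shape class; l_kj is the class's center-connection length
(1 or sqrt 2 pixels) and l_H, l_T are the uncorrected head/tail
connection lengths.  The k_j are calibrated against simulated contours of
known length and vary linearly with resolution, k_j(r) = m_j r + b_j.

:class:`ShapeLengthModel` exposes the calibrated estimator with the
scikit-learn fit/predict API; the module functions are thin wrappers.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .chaincode import ChainCode
from .shapes import CLASS_LABELS, ShapeTally, tally, tally_matrix

__all__ = [
    "SEGMENT_LENGTHS",
    "SQRT2",
    "freeman_length",
    "kulpa_length",
    "corner_length",
    "dna_length",
    "shape_length",
    "coefficients_at",
    "ShapeLengthModel",
    "LinearCoefficientModel",
    "REFERENCE_COEFFICIENT_MODEL",
    "ExtrapolationWarning",
]

SQRT2 = float(np.sqrt(2.0))

#: center-connection length l_kj of each shape class (pixel units):
#: 1 for the direct-center classes k1, k3, k6, k10, sqrt 2 otherwise
SEGMENT_LENGTHS = np.array(
    [1, SQRT2, 1, SQRT2, SQRT2, 1, SQRT2, SQRT2, SQRT2, 1, SQRT2, SQRT2])


class ExtrapolationWarning(UserWarning):
    """Coefficient line model evaluated outside its calibrated range."""


def _counts(arg) -> tuple[int, int]:
    if isinstance(arg, ChainCode):
        return arg.n_even, arg.n_odd
    raise TypeError("expected a ChainCode")


def freeman_length(n_e: int, n_o: int, r: float) -> float:
    """Uncorrected Freeman estimate r(n_e + sqrt(2) n_o)."""
    _check_counts(n_e, n_o, r)
    return r * (n_e + SQRT2 * n_o)


def kulpa_length(n_e: int, n_o: int, r: float) -> float:
    """Kulpa estimate r(0.948 n_e + 1.343 n_o)."""
    _check_counts(n_e, n_o, r)
    return r * (0.948 * n_e + 1.343 * n_o)


def corner_length(n_e: int, n_o: int, n_c: int, r: float) -> float:
    """Corner estimate r(0.980 n_e + 1.406 n_o - 0.091 n_c).

    ``n_c`` counts adjacent unequal chain codes (tight turns).
    """
    _check_counts(n_e, n_o, r)
    if n_c < 0:
        raise ValueError("corner count must be non-negative")
    return r * (0.980 * n_e + 1.406 * n_o - 0.091 * n_c)


def dna_length(n_e: int, n_o: int, r: float, c_f: float) -> float:
    """Factor-corrected estimate C_f * L_F with C_f = <l_c>/L_F."""
    if c_f <= 0:
        raise ValueError("correction factor must be positive")
    return c_f * freeman_length(n_e, n_o, r)


def _check_counts(n_e, n_o, r):
    if n_e < 0 or n_o < 0:
        raise ValueError("connection counts must be non-negative")
    if r <= 0:
        raise ValueError("resolution must be positive")


def shape_length(t: ShapeTally | ChainCode, k: np.ndarray, r: float) -> float:
    """Shape-weighted estimate r(sum_j n_kj k_j l_kj + l_H + l_T)."""
    if isinstance(t, ChainCode):
        t = tally(t)
    k = np.asarray(k, dtype=float)
    if k.shape != (12,):
        raise ValueError("need 12 correction coefficients")
    if r <= 0:
        raise ValueError("resolution must be positive")
    interior = float(t.counts @ (k * SEGMENT_LENGTHS))
    return r * (interior + t.head_length + t.tail_length)


class ShapeLengthModel(BaseEstimator, RegressorMixin):
    """Calibrated shape-weighted contour-length estimator.

    Fitting solves the least-squares system ``r N D K + B = L`` where row
    m of N holds the 12 shape-class occurrence counts of training chain m,
    D = diag(l_k1..l_k12), B the head+tail connection lengths (times r),
    and L the known true contour lengths in nm.

    Parameters
    ----------
    resolution : float
        Pixel resolution r in nm/pixel of the chains the model sees.
    coefficients : array-like of 12 floats, optional
        Fixed k_j to use without fitting (e.g. from a
        :class:`LinearCoefficientModel`).  ``fit`` overwrites them.

    Attributes
    ----------
    coef_ : (12,) ndarray
        Correction coefficients k_1..k_12.
    coef_stderr_ : (12,) ndarray
        Standard errors of the fitted coefficients (NaN for excluded).
    unobserved_ : list of int
        0-based indices of shape classes never seen during fitting; their
        coefficient is pinned to 1 (Freeman weighting) with a warning.
    """

    def __init__(self, resolution: float = 1.0, coefficients=None):
        self.resolution = resolution
        self.coefficients = coefficients

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 14:
            raise ValueError(
                "X must be (m, 14): 12 shape counts plus head/tail lengths; "
                "use sncontour.shapes.tally_matrix to build it from chains")
        return X

    def fit(self, X, y):
        """Calibrate k_1..k_12 on chains of known true length.

        ``X`` is the (m, 14) feature matrix from
        :func:`sncontour.shapes.tally_matrix` (or a list of ChainCode
        objects); ``y`` the true contour lengths in nm.
        """
        if len(X) and isinstance(X[0], ChainCode):
            X = tally_matrix(X)
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (len(X),):
            raise ValueError("y must hold one true length per sample")
        if (y <= 0).any():
            raise ValueError("true lengths must be positive")
        r = float(self.resolution)
        if r <= 0:
            raise ValueError("resolution must be positive")

        N = X[:, :12]
        observed = N.sum(axis=0) > 0
        self.unobserved_ = list(np.nonzero(~observed)[0])
        if self.unobserved_:
            warnings.warn(
                "shape classes "
                + ", ".join(CLASS_LABELS[i] for i in self.unobserved_)
                + " never observed; their coefficients are pinned to 1",
                stacklevel=2)

        # design A = r * N * D restricted to observed columns;
        # target absorbs head/tail lengths and the pinned columns
        A_full = r * N * SEGMENT_LENGTHS
        rhs = y - r * (X[:, 12] + X[:, 13]) - A_full[:, ~observed].sum(axis=1)
        A = A_full[:, observed]
        if np.linalg.matrix_rank(A) < A.shape[1]:
            deficient = [CLASS_LABELS[i] for i in np.nonzero(observed)[0]]
            raise np.linalg.LinAlgError(
                f"singular calibration system over columns {deficient}")
        sol, res, rank, _ = linalg.lstsq(A, rhs)

        coef = np.ones(12)
        coef[observed] = sol
        self.coef_ = coef

        stderr = np.full(12, np.nan)
        dof = len(X) - int(observed.sum())
        if dof > 0:
            resid = rhs - A @ sol
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.pinv(A.T @ A)
            stderr[observed] = np.sqrt(np.diag(cov))
        self.coef_stderr_ = stderr
        self.n_features_in_ = 14
        return self

    def predict(self, X) -> np.ndarray:
        """Estimated contour lengths in nm, one per feature row."""
        if self.coefficients is not None and not hasattr(self, "coef_"):
            self.coef_ = np.asarray(self.coefficients, dtype=float)
            self.unobserved_ = []
        check_is_fitted(self, "coef_")
        if len(X) and isinstance(X[0], ChainCode):
            X = tally_matrix(X)
        X = self._validate_X(X)
        r = float(self.resolution)
        interior = X[:, :12] @ (self.coef_ * SEGMENT_LENGTHS)
        return r * (interior + X[:, 12] + X[:, 13])


class LinearCoefficientModel(BaseEstimator):
    """Per-class linear dependence of k_j on resolution, k_j(r) = m_j r + b_j.

    Attributes after ``fit`` (or construction from slopes/intercepts):
    ``slope_`` and ``intercept_``, each a (12,) ndarray.
    """

    def __init__(self, valid_range: tuple[float, float] = (5.1, 7.8)):
        self.valid_range = valid_range

    def fit(self, r_values, coefficient_sets):
        """Ordinary least-squares line per shape class.

        ``r_values`` is a length-p sequence of resolutions and
        ``coefficient_sets`` a (p, 12) array of calibrated k vectors.
        """
        r = np.asarray(r_values, dtype=float)
        K = np.asarray(coefficient_sets, dtype=float)
        if K.shape != (len(r), 12):
            raise ValueError("coefficient_sets must be (len(r_values), 12)")
        if len(np.unique(r)) < 2:
            raise ValueError("need at least two distinct resolutions")
        A = np.column_stack([r, np.ones_like(r)])
        sol, *_ = linalg.lstsq(A, K)
        self.slope_ = sol[0]
        self.intercept_ = sol[1]
        fitted = A @ sol
        ss_res = ((K - fitted) ** 2).sum(axis=0)
        ss_tot = ((K - K.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.r_squared_ = np.where(ss_tot > 0, 1 - ss_res / ss_tot, 1.0)
        self.residuals_ = K - fitted
        return self

    def coefficients_at(self, r: float) -> np.ndarray:
        """Evaluate k_j(r) = m_j r + b_j, warning outside the valid range."""
        check_is_fitted(self, "slope_")
        if r <= 0:
            raise ValueError("resolution must be positive")
        lo, hi = self.valid_range
        if not lo <= r <= hi:
            warnings.warn(
                f"resolution {r} nm/pixel outside calibrated range "
                f"[{lo}, {hi}]; extrapolating", ExtrapolationWarning,
                stacklevel=2)
        return self.slope_ * r + self.intercept_

    @classmethod
    def from_lines(cls, slopes, intercepts, valid_range=(5.1, 7.8)):
        model = cls(valid_range=valid_range)
        model.slope_ = np.asarray(slopes, dtype=float)
        model.intercept_ = np.asarray(intercepts, dtype=float)
        if model.slope_.shape != (12,) or model.intercept_.shape != (12,):
            raise ValueError("need 12 slopes and 12 intercepts")
        return model

    def to_json(self, path=None) -> str:
        """Serialize as {"k1": {"m": ..., "b": ...}, ...}."""
        check_is_fitted(self, "slope_")
        obj = {
            lab: {"m": float(m), "b": float(b)}
            for lab, m, b in zip(CLASS_LABELS, self.slope_, self.intercept_)
        }
        obj["valid_range"] = list(self.valid_range)
        text = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearCoefficientModel":
        """Load from a JSON string, file path, or open file."""
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                obj = json.loads(s)
            else:
                with open(s) as fh:
                    obj = json.load(fh)
        vr = tuple(obj.get("valid_range", (5.1, 7.8)))
        slopes = [obj[lab]["m"] for lab in CLASS_LABELS]
        intercepts = [obj[lab]["b"] for lab in CLASS_LABELS]
        return cls.from_lines(slopes, intercepts, valid_range=vr)


def coefficients_at(r: float, model: LinearCoefficientModel) -> np.ndarray:
    """Correction coefficients k_1..k_12 at resolution ``r``."""
    return model.coefficients_at(r)


#: reference k_j(r) lines for dsDNA-like contours (persistence length
#: 50 nm), calibrated over r = 5.1-7.8 nm/pixel; shipped as the default
#: coefficient model and overridable by re-calibration.
REFERENCE_COEFFICIENT_MODEL = LinearCoefficientModel.from_lines(
    slopes=[0.0030698, 0.0026365, 0.0025729, -0.0037566, -0.00027806,
            0.010117, 0.0045822, -0.0018511, 0.013175, 0.032808,
            0.015803, 0.042707],
    intercepts=[1.0096, 1.0084, 1.0052, 0.88691, 0.7044, 0.93777,
                0.92897, 0.79905, 0.86184, 0.7165, 0.79656, 0.70788],
)
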