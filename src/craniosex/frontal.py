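"""Frontal sagittal-arc quantification by Fourier shape descriptors.

The midsagittal frontal-bone profile is represented by calibrated 3D
landmarks.  The chain is: least-squares degree-6 polynomial fit of y on x
(refined by Levenberg-Marquardt), projection onto the XY plane, uniform
sampling of the fitted curve into 32 segments, and a 32-point trigonometric
expansion

    A0  = (1/32) sum_m Y_m
    A_k = (1/16) sum_m Y_m cos(2 pi k m / 32)      k = 1..16
    B_k = (1/16) sum_m Y_m sin(2 pi k m / 32)
    P_k = sqrt(A_k^2 + B_k^2),   P'_k = P_k * 100 / A0 ,

whose 16 normalized amplitudes P'_k describe the arc shape independently of
overall skull size (scaling the curve scales P_k and A0 alike).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import least_squares

__all__ = [
    "PolynomialCurve",
    "FourierDescriptor",
    "NormalizationError",
    "fit_polynomial",
    "project_xy",
    "sample_curve",
    "fourier_descriptors",
    "inverse_reconstruct",
    "extract_frontal_features",
]

N_SAMPLES = 32
N_HARMONICS = 16


class NormalizationError(ZeroDivisionError):
    """Descriptor normalization is undefined because A0 = 0."""


@dataclass(frozen=True)
class PolynomialCurve:
    """y = sum_j c_j x^j over [x_min, x_max].

    ``coefficients`` are in the raw x basis (c0..c6, ascending); the
    better-conditioned shifted-and-scaled basis used during fitting is kept
    in ``coefficients_normalized`` (valid on t in [-1, 1] with
    t = (2x - x_min - x_max)/(x_max - x_min)).
    """

    coefficients: np.ndarray
    domain: tuple[float, float]
    coefficients_normalized: np.ndarray | None = None
    residual_rss: float = 0.0

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "coefficients", c)
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("polynomial domain is degenerate")

    def __call__(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.coefficients)


def _validate_landmarks(landmarks) -> np.ndarray:
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("landmarks must be an (n, 3) array of (x, y, z)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("landmarks contain non-finite coordinates")
    if not np.all(np.diff(pts[:, 0]) > 0):
        raise ValueError("landmark x-coordinates must be strictly increasing")
    return pts


def project_xy(landmarks) -> np.ndarray:
    """Project 3D landmarks onto the XY plane (drop z, keep order)."""
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("landmarks must be an (n, 3) array of (x, y, z)")
    return pts[:, :2].copy()


def fit_polynomial(landmarks, degree: int = 6) -> PolynomialCurve:
    """Degree-6 least-squares fit of the projected profile, LM-refined.

    x is mapped to [-1, 1] for conditioning before the linear fit; a
    Levenberg-Marquardt pass on the same residual then refines the
    coefficients (for this linear model it confirms the optimum, so the
    refined residual never exceeds the plain least-squares one).
    """
    pts = _validate_landmarks(landmarks)
    if len(pts) < degree + 1:
        raise ValueError(f"need at least {degree + 1} landmarks for degree {degree}")
    xy = project_xy(pts)
    x, y = xy[:, 0], xy[:, 1]
    lo, hi = float(x[0]), float(x[-1])
    t = (2.0 * x - lo - hi) / (hi - lo)
    V = np.vander(t, degree + 1, increasing=True)
    if np.linalg.matrix_rank(V) < degree + 1:
        raise ValueError("rank-deficient design: duplicate x after scaling")
    coef_lin, *_ = np.linalg.lstsq(V, y, rcond=None)
    rss_lin = float(np.sum((V @ coef_lin - y) ** 2))

    sol = least_squares(lambda c: V @ c - y, coef_lin, method="lm")
    coef_norm = sol.x if 2.0 * sol.cost <= rss_lin else coef_lin
    rss = min(2.0 * float(sol.cost), rss_lin)

    # convert the t-basis coefficients to the raw x basis
    p_norm = Polynomial(coef_norm, domain=[lo, hi], window=[-1, 1])
    coef_raw = p_norm.convert(domain=[lo, hi], kind=Polynomial,
                              window=[lo, hi]).coef
    coef_raw = np.pad(coef_raw, (0, degree + 1 - len(coef_raw)))
    return PolynomialCurve(coefficients=coef_raw, domain=(lo, hi),
                           coefficients_normalized=np.asarray(coef_norm),
                           residual_rss=rss)


def sample_curve(curve: PolynomialCurve, n: int = N_SAMPLES) -> np.ndarray:
    """Evaluate the curve at n uniform half-open grid points.

    Y_m = curve(x_min + m (x_max - x_min)/n) for m = 0..n-1, matching the
    index set of the 32-point expansion.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = curve.domain
    x = lo + np.arange(n) * (hi - lo) / n
    return np.asarray(curve(x), dtype=float)


@dataclass(frozen=True)
class FourierDescriptor:
    """A0 plus 16 (A_k, B_k, P_k, P'_k) quadruples of a 32-sample curve."""

    A0: float
    A: np.ndarray
    B: np.ndarray
    P: np.ndarray
    P_norm: np.ndarray | None   # None when A0 = 0 (normalization undefined)


def fourier_descriptors(samples) -> FourierDescriptor:
    """Shape descriptors of 32 curve samples (see module docstring)."""
    Y = np.asarray(samples, dtype=float)
    if Y.shape != (N_SAMPLES,):
        raise ValueError(f"expected exactly {N_SAMPLES} samples, got {Y.shape}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("samples contain non-finite values")
    m = np.arange(N_SAMPLES)
    k = np.arange(1, N_HARMONICS + 1)[:, None]
    phase = 2.0 * np.pi * k * m / N_SAMPLES
    A0 = float(Y.sum() / N_SAMPLES)
    A = (np.cos(phase) @ Y) / 16.0
    B = (np.sin(phase) @ Y) / 16.0
    P = np.hypot(A, B)
    P_norm = P * 100.0 / A0 if A0 != 0.0 else None
    return FourierDescriptor(A0=A0, A=A, B=B, P=P, P_norm=P_norm)


def inverse_reconstruct(desc: FourierDescriptor, n: int = N_SAMPLES) -> np.ndarray:
    """Resynthesize the 32 samples from the descriptor (exact roundtrip).

    Yhat_m = A0 + sum_{k=1}^{15} [A_k cos(2 pi k m/32) + B_k sin(...)]
             + (A_16 / 2) cos(pi m);
    the Nyquist term carries the 1/2 factor because the forward transform
    used the same 1/16 normalization for k = 16 as for the other harmonics.
    """
    m = np.arange(n)
    k = np.arange(1, N_HARMONICS)[:, None]
    phase = 2.0 * np.pi * k * m / N_SAMPLES
    Y = (desc.A0
         + desc.A[:-1] @ np.cos(phase)
         + desc.B[:-1] @ np.sin(phase)
         + 0.5 * desc.A[-1] * np.cos(np.pi * m))
    return Y


def extract_frontal_features(landmarks, degree: int = 6) -> np.ndarray:
    """Landmarks -> 16 normalized Fourier amplitudes P'_1..P'_16."""
    curve = fit_polynomial(landmarks, degree=degree)
    samples = sample_curve(curve, N_SAMPLES)
    desc = fourier_descriptors(samples)
    if desc.P_norm is None:
        raise NormalizationError("A0 = 0: normalized amplitudes undefined")
    return desc.P_norm
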