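"""Bolus arrival-time estimation by sigmoid wash-in fitting.

The wash-in of the tracer bolus in a voxel is modeled by the four-parameter
sigmoid

    signal(t) = D + (A - D) / (1 + (t/C)**B)

with ``A`` the baseline asymptote, ``D`` the plateau asymptote, ``C`` the
inflection-point abscissa (ms) and ``B`` the dimensionless steepness.  A and
D are held fixed (baseline mean and smoothed peak); only (B, C) are
optimized by nonlinear least squares.  The arrival time t0 — the first
appearance of tracer in the voxel — is the intersection of the tangent at
the inflection point with the baseline level signal = A, which has the
closed form

    t0 = C * (1 - 2/B)

Its uncertainty follows by first-order (delta-method) propagation of the
(B, C) covariance through the gradient (2C/B**2, 1 - 2/B).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import least_squares

from .timecurve import SampledCurve, estimate_baseline, smooth_savitzky_golay

__all__ = [
    "SigmoidFit",
    "ArrivalEstimate",
    "ArrivalMap",
    "LowContrastError",
    "FitConvergenceError",
    "sigmoid_model",
    "fit_sigmoid",
    "arrival_time",
    "estimate_arrival",
    "arrival_map",
]


class LowContrastError(ValueError):
    """Raised when the wash-in contrast D - A is too small to fit."""


class FitConvergenceError(RuntimeError):
    """Raised when the least-squares optimizer fails to converge."""


def sigmoid_model(t: np.ndarray, A: float, D: float, B: float, C: float) -> np.ndarray:
    """Evaluate the wash-in sigmoid D + (A - D)/(1 + (t/C)**B) for t > 0."""
    t = np.asarray(t, dtype=float)
    return D + (A - D) / (1.0 + (t / C) ** B)


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted wash-in sigmoid with the covariance of the free parameters.

    ``cov_BC`` is the 2x2 covariance of (B, C), the Jacobian-based
    estimate J⁺ᵀJ⁺ scaled by the residual variance at the optimum.
    """

    A: float
    D: float
    B: float
    C: float
    cov_BC: np.ndarray
    residual_sd: float
    fit_window: tuple[float, float]

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov_BC, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("cov_BC must be 2x2")
        if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
            raise ValueError("cov_BC must be symmetric")
        object.__setattr__(self, "cov_BC", cov)
        if self.B <= 0 or self.C <= 0:
            raise ValueError("B and C must be positive")
        if self.A == self.D:
            raise ValueError("degenerate fit: A == D")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return sigmoid_model(t, self.A, self.D, self.B, self.C)


@dataclass(frozen=True)
class ArrivalEstimate:
    """Arrival time t0 (ms) with delta-method uncertainty and a quality flag.

    ``quality_flag`` is one of ``ok``, ``low_contrast``, ``edge_of_window``,
    ``unstable``.
    """

    t0: float
    sd_t0: float
    quality_flag: str = "ok"


@dataclass
class ArrivalMap:
    """Voxelwise arrival times over a volume.

    ``t0`` and ``sd`` are float volumes in milliseconds (NaN where no
    estimate was produced); ``quality`` is a boolean mask that is True only
    where a finite, unflagged estimate exists.
    """

    t0: np.ndarray
    sd: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        if not (self.t0.shape == self.sd.shape == self.quality.shape):
            raise ValueError("t0, sd and quality must share a shape")
        bad = self.quality & ~(np.isfinite(self.t0) & np.isfinite(self.sd))
        if np.any(bad):
            raise ValueError("quality mask marks voxels without finite estimates")


def fit_sigmoid(
    curve: SampledCurve,
    A: float,
    D: float,
    fit_window: tuple[float, float] | None = None,
    min_contrast: float = 0.0,
    b_max: float = 100.0,
) -> SigmoidFit:
    """Least-squares fit of (B, C) with baseline A and plateau D fixed.

    The model is monotone in t and can only represent the wash-in, so the
    fit window should end at the (smoothed) peak; by default the whole
    curve is used.  The first sample must be at t > 0.

    Initialization: C0 at the half-height crossing of the data, B0 = 5.
    Bounds: B in (0, ``b_max``], C inside the fit window.  The optimizer is
    a trust-region nonlinear least-squares routine.

    Raises
    ------
    LowContrastError
        If D - A <= ``min_contrast`` (and always if D <= A).
    FitConvergenceError
        If the optimizer reports failure.
    """
    contrast = D - A
    if contrast <= max(min_contrast, 0.0):
        raise LowContrastError(
            f"wash-in contrast D - A = {contrast:.4g} below threshold {min_contrast:.4g}"
        )
    if fit_window is None:
        fit_window = (float(curve.t[0]), float(curve.t[-1]))
    lo, hi = fit_window
    if lo <= 0:
        raise ValueError("fit window must start at t > 0 (model undefined at t <= 0)")
    sel = (curve.t >= lo) & (curve.t <= hi)
    t = curve.t[sel]
    y = curve.y[sel]
    if len(t) < 4:
        raise ValueError("fit window contains fewer than 4 samples")

    half = A + contrast / 2.0
    above = y >= half
    c0 = None
    for i in range(len(t) - 1):
        if not above[i] and above[i + 1]:
            c0 = 0.5 * (t[i] + t[i + 1])
            break
    if c0 is None:
        c0 = float(t[len(t) // 2])
    c_lo, c_hi = float(t[0]), float(t[-1])
    c0 = min(max(c0, c_lo + 1e-9), c_hi - 1e-9)

    def resid(p: np.ndarray) -> np.ndarray:
        return sigmoid_model(t, A, D, p[0], p[1]) - y

    sol = least_squares(
        resid,
        x0=np.array([5.0, c0]),
        bounds=(np.array([1e-6, c_lo]), np.array([b_max, c_hi])),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not sol.success:
        raise FitConvergenceError(f"sigmoid fit did not converge: {sol.message}")
    B, C = float(sol.x[0]), float(sol.x[1])

    dof = max(len(t) - 2, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
    cov = 0.5 * (cov + cov.T)
    return SigmoidFit(
        A=A,
        D=D,
        B=B,
        C=C,
        cov_BC=cov,
        residual_sd=float(np.sqrt(s2)),
        fit_window=(lo, hi),
    )


def arrival_time(fit: SigmoidFit, edge_tol_frames: float = 0.0) -> ArrivalEstimate:
    """Arrival time from the tangent-at-inflection construction.

    The tangent to the fitted sigmoid at t = C intersects the baseline
    level signal = A at t0 = C*(1 - 2/B); steeper wash-ins (larger B) put
    t0 closer to C.  For B <= 2 the construction gives t0 <= 0, which is
    nonphysical, and the estimate is flagged ``unstable``.

    ``sd_t0`` propagates cov(B, C) to first order through
    (dt0/dB, dt0/dC) = (2C/B**2, 1 - 2/B), covariance term included.
    """
    B, C = fit.B, fit.C
    t0 = C * (1.0 - 2.0 / B)
    grad = np.array([2.0 * C / B**2, 1.0 - 2.0 / B])
    var = float(grad @ fit.cov_BC @ grad)
    sd = float(np.sqrt(max(var, 0.0)))
    if B <= 2.0:
        return ArrivalEstimate(t0=float(t0), sd_t0=sd, quality_flag="unstable")
    flag = "ok"
    lo, hi = fit.fit_window
    span = hi - lo
    if t0 < lo - edge_tol_frames or t0 > hi:
        flag = "edge_of_window"
    elif span > 0 and (C > hi - 1e-9 or C < lo + 1e-9):
        flag = "edge_of_window"
    return ArrivalEstimate(t0=float(t0), sd_t0=sd, quality_flag=flag)


def estimate_arrival(
    curve: SampledCurve,
    pre_window: float = 200.0,
    sg_window: float = 150.0,
    sg_order: int = 2,
    min_contrast: float = 0.0,
) -> tuple[ArrivalEstimate, SigmoidFit]:
    """Smooth, fix A and D, fit the sigmoid wash-in and extract t0.

    This is the per-voxel pipeline stage: Savitzky-Golay smoothing, A fixed
    to the pre-bolus baseline mean, D fixed to the plateau level of the
    smoothed curve, the fit window running from the first positive sample
    time to the smoothed peak (wash-in only).

    The plateau level is the mean of the smoothed samples within 2% of the
    smoothed maximum rather than the maximum itself: the maximum of a
    noisy record is biased upward by selection, and that bias propagates
    into the arrival time.
    """
    sm = smooth_savitzky_golay(curve, window=sg_window, poly_order=sg_order)
    A = estimate_baseline(sm, pre_window)
    ipk = int(np.argmax(sm.y))
    D = float(np.mean(sm.y[sm.y >= 0.98 * sm.y[ipk]]))
    lo = float(sm.t[0])
    if lo <= 0:
        lo = float(sm.t[1])
    fit = fit_sigmoid(sm, A=A, D=D, fit_window=(lo, float(sm.t[ipk])), min_contrast=min_contrast)
    return arrival_time(fit), fit


def arrival_map(
    series: np.ndarray,
    mask: np.ndarray,
    frame_interval: float,
    t_start: float | None = None,
    pre_window: float = 200.0,
    sg_window: float = 150.0,
    sg_order: int = 2,
    min_contrast: float = 0.0,
) -> ArrivalMap:
    """Voxelwise arrival-time mapping over a 4D dynamic series.

    Parameters
    ----------
    series : ndarray, shape (X, Y, Z, T)
        Reconstructed dynamic tracer series.
    mask : bool ndarray, shape (X, Y, Z)
        Voxels to analyze.  Voxels whose fit fails (low contrast,
        non-convergence, unstable arrival) are excluded from the quality
        mask rather than raising.
    frame_interval : float
        Frame interval in ms.
    t_start : float, optional
        Time of the first frame; defaults to one frame interval so the
        model domain t > 0 is respected.
    """
    if series.ndim != 4:
        raise ValueError("series must be 4D (X, Y, Z, T)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape[:3]:
        raise ValueError("mask shape must match the spatial grid of the series")
    nt = series.shape[3]
    if t_start is None:
        t_start = frame_interval
    t = t_start + frame_interval * np.arange(nt)

    shape = series.shape[:3]
    t0 = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    quality = np.zeros(shape, dtype=bool)
    # scan order: x fastest, then y, then z
    for z in range(shape[2]):
        for yy in range(shape[1]):
            for x in range(shape[0]):
                if not mask[x, yy, z]:
                    continue
                curve = SampledCurve(t, series[x, yy, z, :], frame_interval)
                try:
                    est, _ = estimate_arrival(
                        curve,
                        pre_window=pre_window,
                        sg_window=sg_window,
                        sg_order=sg_order,
                        min_contrast=min_contrast,
                    )
                except (LowContrastError, FitConvergenceError, ValueError):
                    continue
                t0[x, yy, z] = est.t0
                sd[x, yy, z] = est.sd_t0
                quality[x, yy, z] = est.quality_flag == "ok"
    return ArrivalMap(t0=t0, sd=sd, quality=quality)
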