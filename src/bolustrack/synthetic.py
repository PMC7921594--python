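"""Synthetic first-pass phantoms and cine contour studies with known truth.

The generator emulates the signal structure of a sub-second tracer bolus
passing through the mouse heart and lungs as seen by a fast dynamic
3D acquisition (21.5 ms frame interval, ~1 mm³ voxels):

* the right-ventricle (RV) curve is a gamma-variate bolus — the standard
  indicator-dilution shape — with a configurable FWHM (default 578 ms);
* the left-ventricle (LV) curve is a gamma-variate of the same family,
  delayed by the true pulmonary transit time, broadened to the configured
  FWHM (default 1042 ms, emulating pulmonary dispersion of the bolus) and
  rescaled to the configured peak-amplitude fraction (default 0.58, i.e. a
  42% signal reduction), with an additive sinusoidal cardiac modulation at
  1000/rr_true Hz gated to the post-arrival window;
* the lung curve is intermediate in delay, width and amplitude.

Each curve's arrival time is an explicit parameter of its kernel, so the
truth arrival times are exact by construction (LV arrival is exactly
rv_arrival + ptt_true), never read back off the curves.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .timecurve import SampledCurve

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "CinePhantomConfig",
    "CineStudy",
    "gamma_variate",
    "gamma_variate_fwhm_width_factor",
    "generate_voxel_curve",
    "generate_first_pass_phantom",
    "generate_cine_study",
]

#: gamma-variate shape parameter of the inflow kernel (dimensionless).
#: alpha = 1 gives a sharp, near-linear wash-in foot; the tangent-at-
#: inflection arrival construction locates such a foot to well within one
#: frame, which is what makes phantom ground truth recoverable.
_BOLUS_ALPHA = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of the 4D first-pass phantom.

    Durations are milliseconds; the defaults reproduce the study
    conditions of a mouse first-pass acquisition: 21.5 ms frames over a
    24 x 24 x 12 grid of 1 mm³ voxels, an RV bolus of 578 ms FWHM, an LV
    bolus of 1042 ms FWHM at 58% of the RV amplitude, a pulmonary transit
    time of 745 ms and an RR interval of 133 ms.
    """

    frame_interval: float = 21.5
    n_frames: int = 256
    grid: tuple[int, int, int] = (24, 24, 12)
    rv_arrival: float = 900.0
    ptt_true: float = 745.0
    rv_fwhm: float = 578.0
    lv_fwhm: float = 1042.0
    lv_amplitude_fraction: float = 0.58
    rr_true: float = 133.0
    modulation_depth: float = 0.01
    noise_sd: float = 0.0
    baseline: float = 0.0
    rv_peak: float = 100.0
    lung_amplitude_fraction: float = 0.40
    lung_delay_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for name in ("rv_arrival", "rv_fwhm", "lv_fwhm", "rr_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ptt_true < 0:
            raise ValueError("ptt_true must be nonnegative")
        if not 0 < self.lv_amplitude_fraction <= 1:
            raise ValueError("lv_amplitude_fraction must be in (0, 1]")
        if self.lv_fwhm < self.rv_fwhm:
            raise ValueError("lv_fwhm must not be narrower than rv_fwhm")
        if self.n_frames < 4:
            raise ValueError("n_frames must be at least 4")
        if self.noise_sd < 0 or self.modulation_depth < 0:
            raise ValueError("noise_sd and modulation_depth must be nonnegative")
        duration = self.n_frames * self.frame_interval
        if self.rv_arrival + self.ptt_true >= duration:
            raise ValueError(
                "bolus truncated by the acquisition window: "
                f"rv_arrival + ptt_true = {self.rv_arrival + self.ptt_true:.0f} ms "
                f">= acquisition length {duration:.0f} ms"
            )

    @property
    def frame_times(self) -> np.ndarray:
        """Frame times in ms; the first frame is at one frame interval."""
        return self.frame_interval * (1.0 + np.arange(self.n_frames))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    arrival: dict[str, float]
    ptt: float
    rr: float
    peak_amplitude: dict[str, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "RV" in self.arrival and "LV" in self.arrival:
            if abs((self.arrival["LV"] - self.arrival["RV"]) - self.ptt) > 1e-9:
                raise ValueError("truth arrivals inconsistent with true PTT")


def gamma_variate_fwhm_width_factor(alpha: float) -> float:
    """FWHM of the unit-peak gamma-variate in units of its time-to-peak.

    The gamma-variate normalized to peak 1 at x = t/tp = 1 is
    x**alpha * exp(alpha*(1 - x)); the factor returned is x_right - x_left
    where both solve that expression = 1/2, so FWHM = factor * tp.
    """
    def f(x: float) -> float:
        return x**alpha * np.exp(alpha * (1.0 - x)) - 0.5

    x_left = brentq(f, 1e-12, 1.0)
    # bracket the right root: decays to 0 as x -> inf
    hi = 2.0
    while f(hi) > 0:
        hi *= 2.0
    x_right = brentq(f, 1.0, hi)
    return x_right - x_left


def gamma_variate(
    t: np.ndarray, arrival: float, fwhm: float, peak: float, alpha: float = _BOLUS_ALPHA
) -> np.ndarray:
    """Gamma-variate bolus with given arrival time, FWHM and peak amplitude.

    y(t) = peak * x**alpha * exp(alpha*(1-x)), x = (t - arrival)/tp, t > arrival

    where the time-to-peak tp is solved from the requested FWHM via the
    shape-dependent width factor (FWHM scales linearly with tp at fixed
    alpha).
    """
    tp = fwhm / gamma_variate_fwhm_width_factor(alpha)
    t = np.asarray(t, dtype=float)
    x = (t - arrival) / tp
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = peak * x[pos] ** alpha * np.exp(alpha * (1.0 - x[pos]))
    return out


def _numeric_fwhm(t: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a single-peaked nonnegative curve by linear interpolation."""
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0
    left = right = None
    for i in range(ipk):
        if y[i] < half <= y[i + 1]:
            left = t[i] + (half - y[i]) * (t[i + 1] - t[i]) / (y[i + 1] - y[i])
            break
    for i in range(len(y) - 2, ipk - 1, -1):
        if y[i] >= half > y[i + 1]:
            right = t[i] + (half - y[i]) * (t[i + 1] - t[i]) / (y[i + 1] - y[i])
            break
    if left is None or right is None:
        raise ValueError("curve has no resolvable half-maximum crossings")
    return float(right - left)


def _region_kernel_params(role: str, config: PhantomConfig) -> tuple[float, float, float]:
    """(arrival, fwhm, peak) of the gamma-variate kernel for a region role.

    The lung sits between the ventricles: its delay is a fraction of the
    transit time and its width interpolates between the RV and LV FWHM,
    emulating partial dispersion in the pulmonary bed.
    """
    if role == "RV":
        return config.rv_arrival, config.rv_fwhm, config.rv_peak
    if role == "LV":
        return (
            config.rv_arrival + config.ptt_true,
            config.lv_fwhm,
            config.lv_amplitude_fraction * config.rv_peak,
        )
    if role == "lung":
        f = config.lung_delay_fraction
        return (
            config.rv_arrival + f * config.ptt_true,
            config.rv_fwhm + f * (config.lv_fwhm - config.rv_fwhm),
            config.lung_amplitude_fraction * config.rv_peak,
        )
    raise ValueError(f"unknown region role {role!r}; expected RV, lung or LV")


def _region_clean_curve(role: str, config: PhantomConfig) -> np.ndarray:
    """Noise-free, modulation-free region curve sampled at the frame times."""
    arrival, fwhm, peak = _region_kernel_params(role, config)
    return config.baseline + gamma_variate(config.frame_times, arrival, fwhm, peak)


def _modulation(role: str, config: PhantomConfig) -> np.ndarray:
    """Additive cardiac modulation, gated to the post-arrival window (LV only)."""
    t = config.frame_times
    if role != "LV" or config.modulation_depth == 0:
        return np.zeros_like(t)
    arrival = config.rv_arrival + config.ptt_true
    amp = config.modulation_depth * config.lv_amplitude_fraction * config.rv_peak
    mod = amp * np.sin(2.0 * np.pi * (t - arrival) / config.rr_true)
    mod[t < arrival] = 0.0
    return mod


def generate_voxel_curve(
    role: str, config: PhantomConfig, rng: np.random.Generator | None = None
) -> SampledCurve:
    """Generate the signal-time course of one voxel of the given region.

    ``role`` is ``"RV"``, ``"lung"`` or ``"LV"``.  Noise is additive
    Gaussian with ``config.noise_sd``; with ``rng`` unset a fresh generator
    seeded from ``config.seed`` is used, so repeated calls with the same
    config are identical.
    """
    y = _region_clean_curve(role, config) + _modulation(role, config)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
    return SampledCurve(config.frame_times, y, config.frame_interval)


def _default_masks(grid: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Three disjoint axis-aligned boxes standing in for RV, lung and LV."""
    nx, ny, nz = grid
    if nx < 12 or ny < 6 or nz < 3:
        raise ValueError(f"grid {grid} too small for three disjoint region masks")
    masks = {}
    y0, y1 = ny // 2 - 2, ny // 2 + 1
    z0, z1 = nz // 2 - 1, nz // 2 + 1
    third = nx // 3
    spans = {"RV": (1, third - 1), "lung": (third + 1, 2 * third - 1), "LV": (2 * third + 1, nx - 1)}
    for role, (x0, x1) in spans.items():
        m = np.zeros(grid, dtype=bool)
        m[x0:x1, y0:y1, z0:z1] = True
        masks[role] = m
    return masks


def generate_first_pass_phantom(
    config: PhantomConfig, masks: dict[str, np.ndarray] | None = None
) -> tuple[np.ndarray, PhantomTruth]:
    """Build a 4D (X, Y, Z, T) first-pass series and its ground truth.

    Voxels inside the RV/lung/LV masks carry the corresponding region
    curve plus independent per-voxel noise; background voxels carry the
    baseline plus noise.  The same seed always yields a bit-identical
    series.
    """
    if masks is None:
        masks = _default_masks(config.grid)
    for a in ("RV", "lung", "LV"):
        for b in ("RV", "lung", "LV"):
            if a < b and np.any(masks[a] & masks[b]):
                raise ValueError(f"region masks {a} and {b} overlap")

    rng = np.random.default_rng(config.seed)
    shape = (*config.grid, config.n_frames)
    series = np.full(shape, config.baseline, dtype=float)
    clean = {
        role: _region_clean_curve(role, config) + _modulation(role, config)
        for role in ("RV", "lung", "LV")
    }
    for role in ("RV", "lung", "LV"):
        series[masks[role]] = clean[role]
    if config.noise_sd > 0:
        series += rng.normal(0.0, config.noise_sd, size=shape)

    truth = PhantomTruth(
        arrival={
            "RV": config.rv_arrival,
            "lung": config.rv_arrival + config.lung_delay_fraction * config.ptt_true,
            "LV": config.rv_arrival + config.ptt_true,
        },
        ptt=config.ptt_true,
        rr=config.rr_true,
        peak_amplitude={
            "RV": config.rv_peak,
            "lung": config.lung_amplitude_fraction * config.rv_peak,
            "LV": config.lv_amplitude_fraction * config.rv_peak,
        },
        masks=masks,
    )
    return series, truth


# --------------------------------------------------------------------------
# cine phantom


@dataclass(frozen=True)
class CinePhantomConfig:
    """Short-axis cine phantom: elliptical lumen contours per slice per phase.

    Defaults emulate a healthy mouse left ventricle: 8 slices of 1 mm, a
    5 ms cine phase interval, an RR of 135 ms and semi-axis profiles whose
    diastolic and systolic summed volumes are ~45 µl and ~13.5 µl.
    """

    n_slices: int = 8
    slice_thickness: float = 1.0
    phase_interval: float = 5.0
    rr_true: float = 135.0
    n_phases: int = 55
    diastolic_semi_axes: tuple[tuple[float, float], ...] | None = None
    systolic_semi_axes: tuple[tuple[float, float], ...] | None = None
    n_vertices: int = 64
    vertex_jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.slice_thickness <= 0 or self.phase_interval <= 0:
            raise ValueError("slice count, thickness and phase interval must be positive")
        if self.rr_true <= 0 or self.n_phases < 2 or self.n_vertices < 3:
            raise ValueError("invalid cine phantom timing or vertex count")
        dia = self.diastolic_semi_axes
        sys_ = self.systolic_semi_axes
        if dia is None:
            dia = _default_semi_axes(self.n_slices, total_volume=45.2, thickness=self.slice_thickness)
        if sys_ is None:
            sys_ = tuple(
                (a * np.sqrt(13.5 / 45.2), b * np.sqrt(13.5 / 45.2)) for a, b in dia
            )
        if len(dia) != self.n_slices or len(sys_) != self.n_slices:
            raise ValueError("semi-axis lists must have one entry per slice")
        for (ad, bd), (asys, bsys) in zip(dia, sys_):
            if min(ad, bd, asys, bsys) < 0:
                raise ValueError("semi-axes must be nonnegative")
            if asys * bsys > ad * bd + 1e-12:
                raise ValueError("systolic lumen area exceeds diastolic area")
        object.__setattr__(self, "diastolic_semi_axes", tuple(dia))
        object.__setattr__(self, "systolic_semi_axes", tuple(sys_))


def _default_semi_axes(
    n_slices: int, total_volume: float, thickness: float
) -> tuple[tuple[float, float], ...]:
    """Circular lumen radii with an ellipsoid-like base-to-apex taper."""
    i = np.arange(n_slices)
    center = (n_slices - 1) / 2.0
    profile = 1.0 - (np.abs(i - center) / (n_slices / 2.0 + 0.5)) ** 2
    areas = total_volume / thickness * profile / profile.sum()
    radii = np.sqrt(areas / np.pi)
    return tuple((float(r), float(r)) for r in radii)


@dataclass(frozen=True)
class CineStudy:
    """Generated cine contours plus ground truth.

    ``contours`` maps (slice_index, phase_index) to an (n, 2) vertex array
    in mm.  ``diastole_phase``/``systole_phases`` are the truth phase ids;
    the systole phases are two successive maximal contractions, so their
    separation in phases times the phase interval is the true RR.
    """

    contours: dict[tuple[int, int], np.ndarray]
    slice_thickness: float
    phase_interval: float
    diastole_phase: int
    systole_phases: tuple[int, int]
    true_v_diastole: float
    true_v_systole: float
    rr_true: float

    @property
    def true_v_stroke(self) -> float:
        return self.true_v_diastole - self.true_v_systole


def _ellipse_vertices(
    a: float, b: float, n: int, rng: np.random.Generator, jitter: float
) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    r_jit = rng.normal(0.0, jitter, size=n) if jitter > 0 else 0.0
    x = (a + r_jit) * np.cos(ang)
    y = (b + r_jit) * np.sin(ang)
    return np.column_stack([x, y])


def generate_cine_study(config: CinePhantomConfig) -> CineStudy:
    """Generate polygonal short-axis lumen contours over the cine cycle.

    The per-slice lumen is an ellipse whose area oscillates between the
    systolic and diastolic values with period ``rr_true``; maximal
    contraction occurs at t = 0 and t = rr_true.  True volumes are the
    analytic ellipse volumes (sum of pi*a*b times slice thickness) at the
    reported truth phases, so polygonal approximation error shows up only
    in the measured contours, never in the truth.
    """
    rng = np.random.default_rng(config.seed)
    t = config.phase_interval * np.arange(config.n_phases)
    # 0 at maximal contraction, 1 at maximal dilatation
    s = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / config.rr_true))

    contours: dict[tuple[int, int], np.ndarray] = {}
    for p in range(config.n_phases):
        for sl in range(config.n_slices):
            ad, bd = config.diastolic_semi_axes[sl]
            asys, bsys = config.systolic_semi_axes[sl]
            a = asys + (ad - asys) * s[p]
            b = bsys + (bd - bsys) * s[p]
            contours[(sl, p)] = _ellipse_vertices(
                a, b, config.n_vertices, rng, config.vertex_jitter_mm
            )

    cycle_phases = config.rr_true / config.phase_interval
    if abs(cycle_phases - round(cycle_phases)) > 1e-9:
        raise ValueError("rr_true must be an integer number of phase intervals")
    second_sys = int(round(cycle_phases))
    if second_sys >= config.n_phases:
        raise ValueError("cine study too short to contain two maximal contractions")
    dia_phase = int(np.argmax(s))

    def analytic_volume(scale: float) -> float:
        v = 0.0
        for sl in range(config.n_slices):
            ad, bd = config.diastolic_semi_axes[sl]
            asys, bsys = config.systolic_semi_axes[sl]
            a = asys + (ad - asys) * scale
            b = bsys + (bd - bsys) * scale
            v += np.pi * a * b * config.slice_thickness
        return v

    return CineStudy(
        contours=contours,
        slice_thickness=config.slice_thickness,
        phase_interval=config.phase_interval,
        diastole_phase=dia_phase,
        systole_phases=(0, second_sys),
        true_v_diastole=analytic_volume(float(s[dia_phase])),
        true_v_systole=analytic_volume(float(s[0])),
        rr_true=config.rr_true,
    )
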