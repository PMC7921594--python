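"""Pulmonary transit time, pulmonary blood volume and its error budget.

The pulmonary blood volume (PBV) follows the indicator-dilution identity

    PBV = V_stroke / RR x PTT

— the stroke volume ejected per beat times the number of beats elapsed
while the bolus traverses the pulmonary circulation.  The accompanying
uncertainty is a *maximal error limit*: a worst-case linear sum (not a
quadrature sum) of the propagated error limits of each measured input,

    dPBV = PTT/RR x (dV_dia + dV_sys)            (stroke-volume term)
         + (V_dia - V_sys)/RR x dPTT             (transit-time term)
         + (V_dia - V_sys)/RR x PTT x dRR_rel    (RR term)

with the volume error limits taken as a fraction (default 5%) of the mean
volumes and the RR error as a relative fraction (default 3%).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .arrival import ArrivalEstimate, estimate_arrival
from .timecurve import SampledCurve, smooth_savitzky_golay

__all__ = [
    "RoiSpec",
    "HemodynamicsResult",
    "NonphysiologicalPTTError",
    "place_roi",
    "roi_voxels",
    "pulmonary_transit_time",
    "pulmonary_blood_volume",
    "error_budget",
]


class NonphysiologicalPTTError(ValueError):
    """Raised when the LV arrival does not lag the RV arrival."""


@dataclass(frozen=True)
class RoiSpec:
    """A standardized in-plane ROI centered on the hottest voxel.

    ``extent_mm2`` is the in-plane area covered (default 1 mm², i.e. a
    single voxel at 1 mm resolution); ``center`` is a 0-based (x, y, z)
    voxel index.
    """

    label: str
    center: tuple[int, int, int]
    extent_mm2: float = 1.0
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("RV", "LV"):
            raise ValueError("ROI label must be RV or LV")
        if self.extent_mm2 <= 0:
            raise ValueError("ROI extent must be positive")


@dataclass(frozen=True)
class HemodynamicsResult:
    """PBV with its inputs and maximal-error budget (times ms, volumes µl)."""

    ptt: float
    d_ptt: float
    rr: float
    d_rr_rel: float
    v_diastole: float
    v_systole: float
    v_stroke: float
    d_v_diastole: float
    d_v_systole: float
    pbv: float
    d_v_stroke_term: float
    d_v_transit_term: float
    d_v_rr_term: float
    d_pbv_total: float

    def __post_init__(self) -> None:
        if abs(self.pbv - self.v_stroke / self.rr * self.ptt) > 1e-9 * max(1.0, self.pbv):
            raise ValueError("pbv inconsistent with V_stroke / RR x PTT")
        total = self.d_v_stroke_term + self.d_v_transit_term + self.d_v_rr_term
        if abs(self.d_pbv_total - total) > 1e-9 * max(1.0, total):
            raise ValueError("total error inconsistent with the sum of its terms")
        if min(self.d_v_stroke_term, self.d_v_transit_term, self.d_v_rr_term) < 0:
            raise ValueError("error terms must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def place_roi(
    series: np.ndarray,
    search_mask: np.ndarray,
    label: str,
    frame_interval: float,
    extent_mm2: float = 1.0,
    voxel_size_mm: float = 1.0,
    sg_window: float = 150.0,
) -> RoiSpec:
    """Place a standardized ROI on the maximal smoothed peak signal.

    Each voxel inside ``search_mask`` is temporally smoothed and its peak
    value taken; the ROI is centered on the voxel with the largest peak.
    Ties are broken by scan order (x fastest, then y, then z).
    """
    if series.ndim != 4:
        raise ValueError("series must be 4D (X, Y, Z, T)")
    search_mask = np.asarray(search_mask, dtype=bool)
    if not np.any(search_mask):
        raise ValueError("empty search mask")
    nt = series.shape[3]
    t = frame_interval * (1.0 + np.arange(nt))

    best_val = -np.inf
    best_idx: tuple[int, int, int] | None = None
    # scan order: x fastest, then y, then z; strict > keeps the first maximum
    for z in range(series.shape[2]):
        for y in range(series.shape[1]):
            for x in range(series.shape[0]):
                if not search_mask[x, y, z]:
                    continue
                curve = SampledCurve(t, series[x, y, z, :], frame_interval)
                peak = float(np.max(smooth_savitzky_golay(curve, window=sg_window).y))
                if peak > best_val:
                    best_val = peak
                    best_idx = (x, y, z)
    assert best_idx is not None
    return RoiSpec(
        label=label, center=best_idx, extent_mm2=extent_mm2, slice_index=best_idx[2]
    )


def roi_voxels(roi: RoiSpec, grid: tuple[int, ...], voxel_size_mm: float = 1.0) -> list[tuple[int, int, int]]:
    """Voxel indices covered by the ROI's in-plane extent at its slice.

    The extent is realized as the smallest square block of whole voxels
    whose area is at least ``extent_mm2``, centered on the ROI center and
    clipped to the grid.  At 1 mm resolution the default 1 mm² ROI is the
    single center voxel.
    """
    side = max(1, int(np.ceil(np.sqrt(roi.extent_mm2) / voxel_size_mm)))
    cx, cy, cz = roi.center
    half_lo = (side - 1) // 2
    half_hi = side // 2
    out = []
    for y in range(max(cy - half_lo, 0), min(cy + half_hi + 1, grid[1])):
        for x in range(max(cx - half_lo, 0), min(cx + half_hi + 1, grid[0])):
            out.append((x, y, cz))
    return out


def pulmonary_transit_time(
    arrival_rv: Sequence[ArrivalEstimate],
    arrival_lv: Sequence[ArrivalEstimate],
) -> tuple[float, float]:
    """PTT as the difference of mean ROI arrival times, with its error limit.

    PTT = mean(t0 over LV ROI voxels) - mean(t0 over RV ROI voxels).  The
    maximal PTT error limit adds (linearly) the spread of arrival times
    across each ROI and the mean fit-derived arrival uncertainty; a
    single-voxel ROI has no spread and contributes only its fit-derived
    standard deviation.

    Raises
    ------
    NonphysiologicalPTTError
        If the computed PTT is not positive.
    """
    if len(arrival_rv) == 0 or len(arrival_lv) == 0:
        raise ValueError("both arrival sets must be non-empty")
    t_rv = np.array([e.t0 for e in arrival_rv])
    t_lv = np.array([e.t0 for e in arrival_lv])
    ptt = float(np.mean(t_lv) - np.mean(t_rv))
    sd_rv = float(np.std(t_rv, ddof=1)) if len(t_rv) > 1 else 0.0
    sd_lv = float(np.std(t_lv, ddof=1)) if len(t_lv) > 1 else 0.0
    fit_sds = [e.sd_t0 for e in arrival_rv] + [e.sd_t0 for e in arrival_lv]
    d_ptt = sd_rv + sd_lv + float(np.mean(fit_sds))
    if ptt <= 0:
        raise NonphysiologicalPTTError(
            f"PTT = {ptt:.1f} ms is not positive: LV arrival does not lag RV arrival"
        )
    return ptt, d_ptt


def pulmonary_blood_volume(v_stroke: float, rr: float, ptt: float) -> float:
    """PBV = V_stroke / RR x PTT (µl, with RR and PTT in the same unit)."""
    if v_stroke <= 0 or rr <= 0 or ptt <= 0:
        raise ValueError("stroke volume, RR and PTT must all be positive")
    return v_stroke / rr * ptt


def error_budget(
    v_diastole: float,
    v_systole: float,
    rr: float,
    ptt: float,
    d_ptt: float,
    d_rr_rel: float = 0.03,
    d_vol_rel: float = 0.05,
) -> HemodynamicsResult:
    """Maximal error limit of the PBV as a linear sum of propagated terms.

    The volume error limits are ``d_vol_rel`` (default 5%) of the mean
    diastolic and systolic volumes; the RR error enters as the relative
    fraction ``d_rr_rel`` (default 3%); the transit-time error limit
    ``d_ptt`` is supplied in ms (ROI spread plus fit covariance, see
    :func:`pulmonary_transit_time`).
    """
    if min(v_diastole, v_systole, rr, ptt) <= 0:
        raise ValueError("volumes, RR and PTT must be positive")
    if v_systole > v_diastole:
        raise ValueError("systolic volume exceeds diastolic volume")
    if min(d_ptt, d_rr_rel, d_vol_rel) < 0:
        raise ValueError("error inputs must be nonnegative")
    v_stroke = v_diastole - v_systole
    pbv = pulmonary_blood_volume(v_stroke, rr, ptt)
    d_stroke = ptt / rr * (d_vol_rel * v_diastole + d_vol_rel * v_systole)
    d_transit = v_stroke / rr * d_ptt
    d_rr = v_stroke / rr * ptt * d_rr_rel
    return HemodynamicsResult(
        ptt=float(ptt),
        d_ptt=float(d_ptt),
        rr=float(rr),
        d_rr_rel=float(d_rr_rel),
        v_diastole=float(v_diastole),
        v_systole=float(v_systole),
        v_stroke=float(v_stroke),
        d_v_diastole=float(d_vol_rel * v_diastole),
        d_v_systole=float(d_vol_rel * v_systole),
        pbv=float(pbv),
        d_v_stroke_term=float(d_stroke),
        d_v_transit_term=float(d_transit),
        d_v_rr_term=float(d_rr),
        d_pbv_total=float(d_stroke + d_transit + d_rr),
    )
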