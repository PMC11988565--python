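"""XIC extraction, peak detection/integration and heavy/light ratio tables.

This module plays the role a manually curated Skyline session plays in a
real PRM workflow: turn per-target chromatograms into integrated peak areas
and pair the light (endogenous) and heavy (spiked) channels into the
heavy/light ratio points that feed calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "Peak",
    "RatioPoint",
    "QuantReport",
    "REPORT_COLUMNS",
    "extract_xic",
    "detect_peak",
    "integrate_peak",
    "integrate_window",
    "check_coelution",
    "compute_ratio_table",
    "read_quant_report",
]

#: mandatory columns of the quant-report CSV dialect (see prm_synth)
REPORT_COLUMNS = [
    "peptide",
    "label_type",
    "spike_level_ugml",
    "replicate",
    "area",
    "apex_rt_min",
    "height",
]


@dataclass
class Chromatogram:
    """An extracted-ion chromatogram for one precursor target."""

    times: np.ndarray
    intensities: np.ndarray
    target_mz: float = 0.0
    tolerance: float = 0.1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size < 3:
            raise ValueError("chromatogram needs at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak with integration bounds."""

    apex_rt: float
    left_bound: float
    right_bound: float
    area: float
    height: float
    fwhm: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if not self.left_bound <= self.apex_rt <= self.right_bound:
            raise ValueError("apex must lie within the integration bounds")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass(frozen=True)
class RatioPoint:
    """One calibration observable: spiked heavy level vs heavy/light ratio."""

    heavy_concentration: float
    ratio: float
    replicate: int
    heavy_area: float
    light_area: float


@dataclass
class QuantReport:
    """A parsed quant report: well-formed rows plus a ledger of bad ones."""

    frame: pd.DataFrame
    malformed: list[tuple[int, str]] = field(default_factory=list)


def extract_xic(
    spectra: Sequence[tuple[np.ndarray, np.ndarray, float]],
    target_mz: float,
    tolerance: float = 0.1,
) -> Chromatogram:
    """Sum intensity within ±tolerance (inclusive) of target_mz per spectrum.

    ``spectra`` is a list of (mz array, intensity array, retention time)
    sorted by retention time.
    """
    if not spectra:
        raise ValueError("empty spectra list")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    times, intensities = [], []
    for mz, inten, rt in spectra:
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        mask = np.abs(mz - target_mz) <= tolerance
        times.append(rt)
        intensities.append(float(inten[mask].sum()))
    return Chromatogram(
        times=np.array(times),
        intensities=np.array(intensities),
        target_mz=target_mz,
        tolerance=tolerance,
    )


def _baseline_sd(intensities: np.ndarray) -> float:
    """Robust noise estimate: 1.4826 × median absolute deviation."""
    med = np.median(intensities)
    return 1.4826 * float(np.median(np.abs(intensities - med)))


def detect_peak(
    c: Chromatogram,
    expected_rt_window: Optional[tuple[float, float]] = None,
    boundary_fraction: float = 0.01,
    min_height: Optional[float] = None,
) -> Optional[Peak]:
    """Locate the dominant peak, or return None when nothing rises above noise.

    The apex is the intensity maximum (within ``expected_rt_window`` when
    given).  Bounds extend outward from the apex until intensity drops below
    ``boundary_fraction`` × height or a local valley is reached, whichever
    comes first.  ``min_height`` defaults to 3 × a median-absolute-deviation
    estimate of the baseline noise.  An apex plateau of 3+ samples at the
    maximum is flagged as detector saturation.
    """
    t, y = c.times, c.intensities
    if expected_rt_window is not None:
        lo, hi = expected_rt_window
        window_idx = np.nonzero((t >= lo) & (t <= hi))[0]
        if window_idx.size == 0:
            return None
    else:
        window_idx = np.arange(t.size)
    apex = window_idx[np.argmax(y[window_idx])]
    height = float(y[apex])
    if min_height is None:
        min_height = 3.0 * _baseline_sd(y)
    if height <= 0 or height < min_height:
        return None

    floor = boundary_fraction * height

    def walk(step: int) -> int:
        i = apex
        while True:
            j = i + step
            if j < 0 or j >= t.size:
                return i
            if y[j] <= floor:
                return j
            # local valley: trace starts rising again while already well
            # below the apex — the far side of an adjacent peak
            if y[j] > y[i] and y[i] <= 0.5 * height:
                return i
            i = j

    left = walk(-1)
    right = walk(+1)
    if left == right:
        return None

    # saturation: flat-topped plateau at the apex value
    plateau = np.sum(np.isclose(y[left : right + 1], height, rtol=1e-9, atol=0.0))
    saturated = bool(plateau >= 3)

    area = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
    fwhm = _fwhm(t, y, apex, height)
    return Peak(
        apex_rt=float(t[apex]),
        left_bound=float(t[left]),
        right_bound=float(t[right]),
        area=area,
        height=height,
        fwhm=fwhm,
        saturated=saturated,
    )


def _fwhm(t: np.ndarray, y: np.ndarray, apex: int, height: float) -> float:
    half = height / 2.0
    left_t = t[apex]
    for i in range(apex, 0, -1):
        if y[i - 1] <= half:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left_t = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    else:
        left_t = t[0]
    right_t = t[apex]
    for i in range(apex, len(t) - 1):
        if y[i + 1] <= half:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right_t = t[i] + frac * (t[i + 1] - t[i])
            break
    else:
        right_t = t[-1]
    return float(right_t - left_t)


def integrate_peak(c: Chromatogram, p: Peak) -> float:
    """Trapezoidal integral of intensity over [left_bound, right_bound]."""
    if p.left_bound < c.times[0] - 1e-12 or p.right_bound > c.times[-1] + 1e-12:
        raise ValueError("peak bounds outside chromatogram time range")
    mask = (c.times >= p.left_bound) & (c.times <= p.right_bound)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(c.intensities[mask], c.times[mask]))


def integrate_window(c: Chromatogram, window: tuple[float, float]) -> tuple[float, float]:
    """Trapezoidal area and max intensity over a fixed RT window.

    Fallback measurement when no peak clears the detection threshold; what
    it integrates is the noise floor, which is exactly the flat regime a
    broad calibration curve's segmentation has to find.
    """
    lo, hi = window
    mask = (c.times >= lo) & (c.times <= hi)
    if mask.sum() < 2:
        return 0.0, 0.0
    area = float(np.trapezoid(c.intensities[mask], c.times[mask]))
    return area, float(c.intensities[mask].max())


def check_coelution(
    light: Peak, heavy: Peak, rt_tolerance: float = 0.5
) -> tuple[bool, float]:
    """Apex RT shift (heavy − light) and whether it is within tolerance.

    The tolerance bound is inclusive.  A non-co-eluting pair signals an I/L
    sequence mismatch between the synthetic standard and the endogenous
    peptide (rt_validation territory).
    """
    if light is None or heavy is None:
        raise ValueError("both light and heavy peaks are required")
    shift = heavy.apex_rt - light.apex_rt
    return abs(shift) <= rt_tolerance, shift


def compute_ratio_table(
    report: pd.DataFrame,
) -> tuple[list[RatioPoint], list[tuple[dict, str]]]:
    """Pair light/heavy rows per (spike level, replicate) into RatioPoints.

    Pairs with zero light area are excluded with a reason rather than
    producing an undefined ratio.  Unpaired rows raise.
    """
    missing = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing:
        raise ValueError(f"report missing mandatory columns: {missing}")
    points: list[RatioPoint] = []
    excluded: list[tuple[dict, str]] = []
    for (level, rep), group in report.groupby(
        ["spike_level_ugml", "replicate"], sort=True
    ):
        by_type = {lt: g for lt, g in group.groupby("label_type")}
        if "light" not in by_type or "heavy" not in by_type:
            raise ValueError(
                f"unpaired rows at level {level}, replicate {rep}: "
                f"have {sorted(by_type)}"
            )
        light_area = float(by_type["light"]["area"].iloc[0])
        heavy_area = float(by_type["heavy"]["area"].iloc[0])
        record = {
            "spike_level_ugml": float(level),
            "replicate": int(rep),
            "light_area": light_area,
            "heavy_area": heavy_area,
        }
        if light_area <= 0:
            excluded.append((record, "zero_light_area"))
            continue
        points.append(
            RatioPoint(
                heavy_concentration=float(level),
                ratio=heavy_area / light_area,
                replicate=int(rep),
                heavy_area=heavy_area,
                light_area=light_area,
            )
        )
    return points, excluded


def read_quant_report(path) -> QuantReport:
    """Read a quant-report CSV (see prm_synth for the dialect).

    Unknown columns are preserved; rows with unparseable numeric cells are
    collected with their 1-based data line numbers instead of being
    silently dropped.
    """
    frame = pd.read_csv(
        path, dtype={"peptide": str, "label_type": str}, float_precision="round_trip"
    )
    missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"quant report missing mandatory column(s): {missing}")
    numeric = ["spike_level_ugml", "replicate", "area", "apex_rt_min", "height"]
    for col in numeric:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    bad_mask = frame[numeric].isna().any(axis=1)
    malformed = [
        (int(idx) + 1, "unparseable numeric cell") for idx in frame.index[bad_mask]
    ]
    frame = frame[~bad_mask].copy()
    frame["replicate"] = frame["replicate"].astype(int)
    return QuantReport(frame=frame, malformed=malformed)
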