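"""Broad and refined in-sample calibration curves.

The reversed in-sample design fits the heavy/light peak-area ratio against
the spiked heavy on-column concentration and reads off the endogenous
concentration where the fitted line crosses ratio = 1 (equal heavy and
light amounts).  A broad curve spans many log-spaced levels, most of which
fall either in the noise floor (below the segmented-regression breakpoint
ψ) or in detector saturation; the surviving linear window yields a first
estimate and an LOQ, and a refined geometric ladder centred on that
estimate yields the authoritative quantification.

Two LOQ conventions are implemented: the breakpoint ψ itself for broad
curves, and 10·s0/slope (s0 = standard deviation of the predicted ratio at
the y-intercept) for refined curves where segmentation is impossible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .peak_integration import RatioPoint, compute_ratio_table
from .peptide_chem import Peptide
from .prm_synth import SpikePlan

__all__ = [
    "CalibrationError",
    "LineFit",
    "SegmentedFit",
    "CalibrationCurve",
    "QuantEstimate",
    "TwoStageResult",
    "fit_line",
    "segment_breakpoint",
    "select_linear_range",
    "build_curve",
    "loq_from_breakpoint",
    "loq_from_slope_sd",
    "inverse_estimate",
    "design_refined_levels",
    "quantify_broad",
    "quantify_refined",
    "run_two_stage",
]


class CalibrationError(ValueError):
    """Raised when a calibration curve cannot be built or used."""


@dataclass(frozen=True)
class LineFit:
    """Ordinary least squares fit y = b0 + b1·x."""

    intercept: float
    slope: float
    covariance: np.ndarray  # 2x2, order (intercept, slope)
    residual_sd: float
    r_squared: float
    n: int


def fit_line(
    points: Sequence[tuple[float, float]],
    cov_type: str = "nonrobust",
    weights: Optional[Sequence[float]] = None,
) -> LineFit:
    """Least-squares line through (x, y) points; needs >= 3 points and
    >= 2 distinct x so the residual variance is determined.

    ``cov_type`` selects the parameter covariance estimator: classical
    ("nonrobust") or any statsmodels heteroscedasticity-consistent form
    ("HC3" is what the calibration pipeline uses, because area-ratio noise
    is multiplicative and therefore grows with concentration).  ``weights``
    switches to WLS (e.g. 1/x weighting).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise CalibrationError("need at least 3 points to fit a line")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate fit: all x values equal")
    X = sm.add_constant(x)
    if weights is not None:
        model = sm.WLS(y, X, weights=np.asarray(weights, dtype=float))
    else:
        model = sm.OLS(y, X)
    if cov_type == "nonrobust":
        res = model.fit()
    else:
        res = model.fit(cov_type=cov_type)
    resid_sd = math.sqrt(res.ssr / res.df_resid) if res.df_resid > 0 else 0.0
    return LineFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        covariance=np.asarray(res.cov_params()),
        residual_sd=resid_sd,
        r_squared=float(res.rsquared),
        n=len(x),
    )


@dataclass(frozen=True)
class SegmentedFit:
    """Two-segment piecewise-linear fit with breakpoint ψ.

    By default the two segments are fit independently (a discontinuity at ψ
    is allowed); ψ is placed at the intersection of the two lines when that
    falls inside the gap between the bracketing data points, else at the
    gap midpoint.  ``no_breakpoint`` is set when splitting does not improve
    on a single line (F-test) — the fit is still reported but must not be
    used as an LOQ.
    """

    psi: float
    left_intercept: float
    left_slope: float
    right_intercept: float
    right_slope: float
    rss: float
    n_left: int
    n_right: int
    rss_single: float
    no_breakpoint: bool = False
    transform: str = "linear"


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: returns (intercept, slope, rss)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        return ym, 0.0, float(((y - ym) ** 2).sum())
    b1 = float(((x - xm) * (y - ym)).sum()) / sxx
    b0 = ym - b1 * xm
    resid = y - b0 - b1 * x
    return b0, b1, float((resid**2).sum())


def segment_breakpoint(
    points: Sequence[tuple[float, float]],
    min_points_side: int = 2,
    alpha: float = 0.01,
    transform: str = "linear",
    mode: str = "free",
) -> SegmentedFit:
    """Find the breakpoint between the noise floor and the linear response.

    Searches every admissible partition of the sorted points into a left
    and a right segment (each needing >= ``min_points_side`` points over
    >= 2 distinct x), fits a free line to each side and keeps the split
    with the smallest total RSS; RSS ties go to the smaller ψ.  Because the
    segments are free lines, this partition sweep is exhaustive: RSS
    depends only on which points fall on which side, so a denser ψ grid
    cannot do better.

    ``transform="log"`` runs the search on (log10 x, log10 y), the natural
    space for a log-spaced spike ladder with multiplicative noise (on
    linear axes the top levels would dominate the RSS and swamp the noise
    floor entirely).  ψ is always returned in original concentration
    units; segment slopes/intercepts are in the fitting space recorded by
    ``SegmentedFit.transform``.

    ``mode="continuous"`` instead fits a hinge model
    y = b0 + b1·x + b2·max(0, x−ψ) whose segments meet at ψ, optimising ψ
    by a grid over the inter-point gaps followed by bounded scalar
    refinement; ψ is then a genuine continuous parameter rather than a
    partition boundary.
    """
    pts = sorted((float(x), float(y)) for x, y in points)
    if len(pts) < 5:
        raise CalibrationError("need at least 5 points for segmentation")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if transform == "log":
        if np.any(x <= 0) or np.any(y <= 0):
            raise CalibrationError("log transform requires positive x and y")
        x, y = np.log10(x), np.log10(y)
    elif transform != "linear":
        raise ValueError(f"unknown transform {transform!r}")
    xs = np.unique(x)
    if xs.size < 4:
        raise CalibrationError("need at least 4 distinct x for segmentation")

    b0s, b1s, rss_single = _ols_rss(x, y)

    if mode == "continuous":
        return _segment_continuous(x, y, xs, rss_single, alpha, transform)
    if mode != "free":
        raise ValueError(f"unknown mode {mode!r}")

    best = None
    for cut in range(1, xs.size):
        left_mask = x <= xs[cut - 1]
        lx, ly = x[left_mask], y[left_mask]
        rx, ry = x[~left_mask], y[~left_mask]
        if (
            lx.size < min_points_side
            or rx.size < min_points_side
            or np.unique(lx).size < 2
            or np.unique(rx).size < 2
        ):
            continue
        lb0, lb1, lrss = _ols_rss(lx, ly)
        rb0, rb1, rrss = _ols_rss(rx, ry)
        total = lrss + rrss
        if best is None or total < best[0] - 1e-15 * max(1.0, abs(best[0])):
            gap = (float(lx.max()), float(rx.min()))
            best = (total, gap, (lb0, lb1), (rb0, rb1), lx.size, rx.size)
    if best is None:
        raise CalibrationError("no admissible breakpoint candidate")

    total, (gl, gr), (lb0, lb1), (rb0, rb1), nl, nr = best
    # place ψ at the intersection of the two lines when it falls in the gap
    psi = 0.5 * (gl + gr)
    if abs(rb1 - lb1) > 0:
        x_star = (lb0 - rb0) / (rb1 - lb1)
        if gl <= x_star <= gr:
            psi = x_star

    no_break = False
    if rss_single <= 1e-12 * max(1.0, float((y**2).sum())):
        no_break = True  # a single line already fits perfectly
    elif total > 0:
        dof = len(pts) - 4
        if dof > 0:
            f = ((rss_single - total) / 2.0) / (total / dof)
            no_break = scipy.stats.f.sf(f, 2, dof) > alpha
    if transform == "log":
        psi = 10.0**psi
    return SegmentedFit(
        psi=float(psi),
        left_intercept=lb0,
        left_slope=lb1,
        right_intercept=rb0,
        right_slope=rb1,
        rss=total,
        n_left=nl,
        n_right=nr,
        rss_single=rss_single,
        no_breakpoint=no_break,
        transform=transform,
    )


def _segment_continuous(
    x: np.ndarray,
    y: np.ndarray,
    xs: np.ndarray,
    rss_single: float,
    alpha: float,
    transform: str,
) -> SegmentedFit:
    """Hinge-model segmentation: segments constrained to meet at ψ."""

    def hinge_rss(psi: float) -> tuple[float, np.ndarray]:
        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta

    candidates = 0.5 * (xs[:-1] + xs[1:])
    scored = sorted((hinge_rss(c)[0], c) for c in candidates)
    _, best_c = scored[0]
    i = int(np.searchsorted(xs, best_c))
    lo = xs[max(i - 2, 0)]
    hi = xs[min(i + 1, xs.size - 1)]
    res = scipy.optimize.minimize_scalar(
        lambda p: hinge_rss(p)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10 * max(1.0, hi - lo)},
    )
    psi = float(res.x)
    rss, beta = hinge_rss(psi)
    n_left = int(np.sum(x < psi))
    n_right = int(x.size - n_left)
    no_break = False
    if rss_single <= 1e-12 * max(1.0, float((y**2).sum())):
        no_break = True
    elif rss > 0:
        dof = x.size - 4
        if dof > 0:
            f = ((rss_single - rss) / 2.0) / (rss / dof)
            no_break = scipy.stats.f.sf(f, 2, dof) > alpha
    if transform == "log":
        psi_out = 10.0**psi
    else:
        psi_out = psi
    return SegmentedFit(
        psi=float(psi_out),
        left_intercept=float(beta[0]),
        left_slope=float(beta[1]),
        right_intercept=float(beta[0] - beta[2] * psi),
        right_slope=float(beta[1] + beta[2]),
        rss=rss,
        n_left=n_left,
        n_right=n_right,
        rss_single=rss_single,
        no_breakpoint=no_break,
        transform=transform,
    )


def select_linear_range(
    points: Sequence[RatioPoint],
    seg: Optional[SegmentedFit],
    saturation_flags: Optional[Iterable[bool]] = None,
    manual_exclusions: Optional[Iterable[RatioPoint]] = None,
) -> tuple[list[RatioPoint], list[tuple[RatioPoint, str]]]:
    """Retain points inside the linear response window.

    Points below the breakpoint ψ are excluded (``below_breakpoint``),
    saturated points are excluded (``saturated``), and explicit manual
    exclusions are honoured.  Every input point lands in exactly one of the
    two output lists.
    """
    points = list(points)
    flags = list(saturation_flags) if saturation_flags is not None else [False] * len(points)
    if len(flags) != len(points):
        raise ValueError("saturation_flags length mismatch")
    manual = set(id(p) for p in manual_exclusions) if manual_exclusions else set()
    retained: list[RatioPoint] = []
    excluded: list[tuple[RatioPoint, str]] = []
    for p, sat in zip(points, flags):
        if id(p) in manual:
            excluded.append((p, "manual"))
        elif seg is not None and not seg.no_breakpoint and p.heavy_concentration < seg.psi:
            excluded.append((p, "below_breakpoint"))
        elif sat:
            excluded.append((p, "saturated"))
        else:
            retained.append(p)
    if len(retained) < 3:
        raise CalibrationError(
            f"only {len(retained)} points survive range selection; "
            "redesign a refined spike ladder inside the linear range"
        )
    return retained, excluded


@dataclass
class CalibrationCurve:
    """A fitted ratio-vs-concentration line over the retained points."""

    points: list[RatioPoint]
    fit: LineFit
    excluded: list[tuple[RatioPoint, str]]
    stage: str  # "broad" | "refined"
    loq: Optional[float] = None
    segmented: Optional[SegmentedFit] = None

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def intercept(self) -> float:
        return self.fit.intercept

    @property
    def r_squared(self) -> float:
        return self.fit.r_squared


def build_curve(
    points: Sequence[RatioPoint],
    stage: str,
    excluded: Optional[Sequence[tuple[RatioPoint, str]]] = None,
    segmented: Optional[SegmentedFit] = None,
    cov_type: str = "HC3",
    weighting: str = "none",
) -> CalibrationCurve:
    """Fit the calibration line on replicate-level retained points.

    Replicates are deliberately not averaged: each injection contributes
    its own point so the residual variance reflects injection-to-injection
    scatter.  The regression is unweighted by default (``weighting="1/x"``
    switches to WLS) but its covariance is heteroscedasticity-consistent,
    which keeps the inverse-prediction interval honest under the
    constant-CV noise typical of area ratios.
    """
    points = list(points)
    xs = [p.heavy_concentration for p in points]
    weights = None
    if weighting == "1/x":
        weights = [1.0 / x for x in xs]
    elif weighting != "none":
        raise ValueError(f"unknown weighting {weighting!r}")
    fit = fit_line(
        [(p.heavy_concentration, p.ratio) for p in points],
        cov_type=cov_type,
        weights=weights,
    )
    if fit.slope <= 0:
        raise CalibrationError("calibration slope must be positive")
    return CalibrationCurve(
        points=points,
        fit=fit,
        excluded=list(excluded) if excluded else [],
        stage=stage,
        segmented=segmented,
    )


def loq_from_breakpoint(seg: SegmentedFit) -> float:
    """Broad-curve LOQ: the breakpoint ψ between noise and linear response."""
    if seg.no_breakpoint:
        raise CalibrationError("no breakpoint detected; LOQ undefined")
    return seg.psi


def loq_from_slope_sd(curve: CalibrationCurve) -> float:
    """Refined-curve LOQ: 10·s0/slope, s0 the SD of the predicted ratio at
    the y-intercept (from the fit covariance).

    This is the conventional signal-to-noise form; dividing slope by s0
    instead would make the LOQ improve as noise grows.
    """
    if curve.fit.slope <= 0:
        raise CalibrationError("slope must be positive for an LOQ")
    s0 = math.sqrt(float(curve.fit.covariance[0, 0]))
    return 10.0 * s0 / curve.fit.slope


@dataclass
class QuantEstimate:
    """Endogenous concentration from inverse prediction at a target ratio."""

    concentration: float
    standard_error: float
    ci95: tuple[float, float]
    stage: str
    peptide: Optional[Peptide] = None
    extrapolated: bool = False
    flags: list[str] = field(default_factory=list)


def inverse_estimate(
    curve: CalibrationCurve,
    target_ratio: float = 1.0,
    peptide: Optional[Peptide] = None,
    fieller: bool = False,
) -> QuantEstimate:
    """Read the concentration where the fitted line crosses ``target_ratio``.

    At ratio 1 the spiked heavy equals the endogenous light, so x̂ =
    (1 − b0)/b1 is the endogenous concentration.  The standard error comes
    from first-order (delta) propagation of the (b0, b1) covariance;
    ``fieller=True`` replaces the ±1.96·se interval with a Fieller
    interval, which stays honest when the slope is poorly determined.
    """
    b0, b1 = curve.fit.intercept, curve.fit.slope
    if b1 <= 0:
        raise CalibrationError("slope must be positive for inverse estimation")
    x_hat = (target_ratio - b0) / b1
    cov = curve.fit.covariance
    g = np.array([-1.0 / b1, -(target_ratio - b0) / b1**2])
    var = float(g @ cov @ g)
    se = math.sqrt(max(var, 0.0))
    z = 1.96
    ci = (x_hat - z * se, x_hat + z * se)
    if fieller:
        ci = _fieller_interval(b0, b1, cov, target_ratio, z) or ci
    ratios = [p.ratio for p in curve.points]
    extrapolated = not (min(ratios) <= target_ratio <= max(ratios))
    flags = ["extrapolated_target_ratio"] if extrapolated else []
    if x_hat <= 0:
        flags.append("non_positive_estimate")
    return QuantEstimate(
        concentration=x_hat,
        standard_error=se,
        ci95=ci,
        stage=curve.stage,
        peptide=peptide,
        extrapolated=extrapolated,
        flags=flags,
    )


def _fieller_interval(
    b0: float, b1: float, cov: np.ndarray, target: float, z: float
) -> Optional[tuple[float, float]]:
    """Fieller confidence set for (target − b0)/b1; None when unbounded."""
    a = target - b0
    v00, v11, v01 = cov[0, 0], cov[1, 1], cov[0, 1]
    # quadratic in x: (b1 x - a)^2 - z^2 (v00 + 2 x v01·(-1)·... ) — derive
    # from var(a - b1 x) = v00 + x^2 v11 + 2 x v01 (since d(a)/db0 = -1,
    # cov(a, b1) = -v01)
    A = b1**2 - z**2 * v11
    B = -2 * a * b1 + 2 * z**2 * v01
    C = a**2 - z**2 * v00
    if A <= 0:
        return None
    disc = B**2 - 4 * A * C
    if disc < 0:
        return None
    r = math.sqrt(disc)
    return ((-B - r) / (2 * A), (-B + r) / (2 * A))


def design_refined_levels(
    broad_estimate: float,
    n_levels: int = 5,
    factor: float = 2.0,
    peptide: Optional[Peptide] = None,
    replicates: int = 3,
) -> SpikePlan:
    """Geometric spike ladder centred on the broad estimate:
    estimate · factor^k for k = −(n−1)/2 .. +(n−1)/2."""
    if broad_estimate <= 0:
        raise CalibrationError("broad estimate must be positive")
    if n_levels < 1 or n_levels % 2 == 0:
        raise ValueError("n_levels must be a positive odd integer")
    if factor <= 1 and n_levels > 1:
        raise ValueError("factor must be > 1 for a non-degenerate ladder")
    half = (n_levels - 1) // 2
    levels = [broad_estimate * factor**k for k in range(-half, half + 1)]
    return SpikePlan(levels=levels, replicates=replicates, peptide=peptide)


def _rt_shift_flag(report: pd.DataFrame, rt_tolerance: float) -> Optional[float]:
    """Median heavy−light apex shift when it exceeds the co-elution
    tolerance, else None.  Only pairs where both channels produced a real
    peak (distinct apex values) are informative; a persistent shift means
    the synthetic standard and the endogenous peptide differ in sequence
    (I/L isoforms) and the pair should go through rt_validation."""
    pivot = report.pivot_table(
        index=["spike_level_ugml", "replicate"],
        columns="label_type",
        values="apex_rt_min",
        aggfunc="first",
    )
    if "light" not in pivot.columns or "heavy" not in pivot.columns:
        return None
    shifts = (pivot["heavy"] - pivot["light"]).dropna()
    if shifts.empty:
        return None
    med = float(shifts.median())
    return med if abs(med) > rt_tolerance else None


def _saturation_flags(
    report: pd.DataFrame, points: Sequence[RatioPoint], ceiling: Optional[float]
) -> list[bool]:
    """Flag ratio points whose heavy peak apex reached the detector ceiling."""
    if ceiling is None:
        return [False] * len(points)
    heavy = report[report["label_type"] == "heavy"]
    sat_keys = {
        (float(r["spike_level_ugml"]), int(r["replicate"]))
        for _, r in heavy.iterrows()
        if float(r["height"]) >= 0.999 * ceiling
    }
    return [(p.heavy_concentration, p.replicate) in sat_keys for p in points]


def quantify_broad(
    report: pd.DataFrame,
    saturation_ceiling: Optional[float] = None,
    peptide: Optional[Peptide] = None,
    rt_tolerance: float = 0.5,
) -> tuple[CalibrationCurve, QuantEstimate]:
    """Broad-stage pipeline: segmentation on the heavy areas, linear-range
    selection, ratio fit, LOQ = ψ, inverse estimate at ratio 1.

    A persistent heavy-vs-light apex shift is flagged
    (``heavy_light_rt_mismatch``) but does not block quantification: a
    sequence-isoform pair can still be calibrated, only without the
    guarantee of identical matrix effects.
    """
    points, pair_excluded = compute_ratio_table(report)
    seg = segment_breakpoint(
        [(p.heavy_concentration, p.heavy_area) for p in points], transform="log"
    )
    flags = _saturation_flags(report, points, saturation_ceiling)
    retained, excluded = select_linear_range(points, seg, flags)
    curve = build_curve(retained, "broad", excluded=excluded, segmented=seg)
    curve.loq = loq_from_breakpoint(seg) if not seg.no_breakpoint else None
    est = inverse_estimate(curve, 1.0, peptide=peptide)
    if curve.loq is not None and est.concentration < curve.loq:
        est.flags.append("estimate_below_loq")
    if _rt_shift_flag(report, rt_tolerance) is not None:
        est.flags.append("heavy_light_rt_mismatch")
    return curve, est


def quantify_refined(
    report: pd.DataFrame,
    saturation_ceiling: Optional[float] = None,
    peptide: Optional[Peptide] = None,
    rt_tolerance: float = 0.5,
) -> tuple[CalibrationCurve, QuantEstimate]:
    """Refined-stage pipeline: no segmentation (the ladder is inside the
    linear range by design), LOQ = 10·s0/slope, inverse estimate at ratio 1.
    A ladder that fails to bracket ratio 1 is flagged, not fatal."""
    points, _ = compute_ratio_table(report)
    flags = _saturation_flags(report, points, saturation_ceiling)
    retained, excluded = select_linear_range(points, None, flags)
    curve = build_curve(retained, "refined", excluded=excluded)
    curve.loq = loq_from_slope_sd(curve)
    est = inverse_estimate(curve, 1.0, peptide=peptide)
    ratios = [p.ratio for p in retained]
    if not (min(ratios) <= 1.0 <= max(ratios)):
        est.flags.append("refined_levels_do_not_bracket_ratio_1")
    if _rt_shift_flag(report, rt_tolerance) is not None:
        est.flags.append("heavy_light_rt_mismatch")
    return curve, est


@dataclass
class TwoStageResult:
    broad_curve: CalibrationCurve
    broad_estimate: QuantEstimate
    refined_curve: CalibrationCurve
    refined_estimate: QuantEstimate

    @property
    def disagreement_factor(self) -> float:
        """Fold difference between the stages; the refined estimate is the
        authoritative one — the disagreement is reported, never corrected."""
        b, r = self.broad_estimate.concentration, self.refined_estimate.concentration
        if b <= 0 or r <= 0:
            return math.inf
        return max(b / r, r / b)


def run_two_stage(
    broad_report: pd.DataFrame,
    refined_report: pd.DataFrame,
    saturation_ceiling: Optional[float] = None,
    peptide: Optional[Peptide] = None,
) -> TwoStageResult:
    """Broad estimate first, then the refined curve built around it."""
    broad_curve, broad_est = quantify_broad(
        broad_report, saturation_ceiling, peptide=peptide
    )
    refined_curve, refined_est = quantify_refined(
        refined_report, saturation_ceiling, peptide=peptide
    )
    return TwoStageResult(
        broad_curve=broad_curve,
        broad_estimate=broad_est,
        refined_curve=refined_curve,
        refined_estimate=refined_est,
    )
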