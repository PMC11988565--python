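import math

import numpy as np
import pytest

from prmquant.calibration import (
    CalibrationCurve,
    CalibrationError,
    LineFit,
    design_refined_levels,
    fit_line,
    inverse_estimate,
    loq_from_breakpoint,
    loq_from_slope_sd,
    quantify_broad,
    quantify_refined,
    run_two_stage,
    segment_breakpoint,
    select_linear_range,
    build_curve,
)
from prmquant.peak_integration import RatioPoint
from prmquant.prm_synth import (
    SimConfig,
    SpikePlan,
    default_broad_levels,
    simulate_piecewise_response,
    simulate_quant_report,
)


# --- straight-line fitting -----------------------------------------------

def test_exact_line_recovered():
    fit = fit_line([(x, 2 * x + 1) for x in (0.0, 1.0, 2.0, 3.0)])
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0)


def _closed_form_ols(points):
    """Independent closed-form OLS oracle (normal equations)."""
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(x) - 2)
    return beta, s2 * np.linalg.inv(X.T @ X)


def test_fit_matches_closed_form_and_duplication_halves_variance():
    rng = np.random.default_rng(11)
    points = [(x, 3 * x + 0.5 + rng.normal(0, 0.2)) for x in np.linspace(0, 1, 6)]
    beta, cov = _closed_form_ols(points)
    fit = fit_line(points)
    assert fit.intercept == pytest.approx(beta[0])
    assert fit.slope == pytest.approx(beta[1])
    assert np.allclose(fit.covariance, cov)
    dup_beta, dup_cov = _closed_form_ols(points + points)
    dup = fit_line(points + points)
    assert dup.slope == pytest.approx(fit.slope)
    assert np.allclose(dup.covariance, dup_cov)
    # doubling every point scales the classical covariance by (n-2)/(2n-2)·...
    # the oracle captures the exact factor; it is close to 1/2
    assert dup_cov[1, 1] / cov[1, 1] == pytest.approx(0.5, rel=0.3)


def test_underdetermined_and_degenerate_fits_rejected():
    with pytest.raises(CalibrationError):
        fit_line([(0, 0), (1, 1)])
    with pytest.raises(CalibrationError):
        fit_line([(1, 0), (1, 1), (1, 2)])


# --- segmentation --------------------------------------------------------

def test_constructed_break_recovered_exactly():
    xs = np.arange(0.2, 2.01, 0.2)
    pts = [(x, 0.0 if x < 1 else 2 * (x - 1)) for x in xs]
    seg = segment_breakpoint(pts)
    assert seg.psi == pytest.approx(1.0, abs=0.2)  # within grid resolution
    assert not seg.no_breakpoint
    assert loq_from_breakpoint(seg) == seg.psi


def test_single_line_reports_no_breakpoint():
    pts = [(x, 2 * x + 1) for x in np.arange(0.2, 2.01, 0.2)]
    seg = segment_breakpoint(pts)
    assert seg.no_breakpoint
    with pytest.raises(CalibrationError):
        loq_from_breakpoint(seg)


def test_segmentation_needs_enough_points():
    with pytest.raises(CalibrationError):
        segment_breakpoint([(0, 0), (1, 0), (2, 1), (3, 2)])


def _brute_force_rss(points):
    """Dense-grid oracle: for every candidate ψ on a fine grid, split the
    points and fit a free line per side; return the minimal total RSS."""
    pts = sorted(points)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])

    def rss_of(mask):
        def side(xs, ys):
            X = np.column_stack([np.ones_like(xs), xs])
            beta, res, *_ = np.linalg.lstsq(X, ys, rcond=None)
            r = ys - X @ beta
            return float(r @ r)

        return side(x[mask], y[mask]) + side(x[~mask], y[~mask])

    best = math.inf
    for psi in np.linspace(x.min(), x.max(), 2000):
        mask = x <= psi
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        if np.unique(x[mask]).size < 2 or np.unique(x[~mask]).size < 2:
            continue
        best = min(best, rss_of(mask))
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_partition_search_matches_dense_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 13))
    x = np.sort(rng.uniform(0, 10, n))
    y = np.where(x < 4, 1.0, 1.0 + 1.5 * (x - 4)) + rng.normal(0, 0.3, n)
    pts = list(zip(x, y))
    seg = segment_breakpoint(pts)
    assert seg.rss <= _brute_force_rss(pts) * (1 + 1e-6)


def test_noisy_piecewise_breakpoint_recovery_small():
    levels = default_broad_levels()
    psi_true = levels[3] * (levels[4] / levels[3]) ** 0.3  # off-centre in the gap
    spacing = levels[4] - levels[3]
    rng = np.random.default_rng(21)
    errs = []
    for _ in range(20):
        x, y = simulate_piecewise_response(
            levels, psi_true, slope=7e5, floor=36.0, cv=0.05, replicates=3, rng=rng
        )
        seg = segment_breakpoint(list(zip(x, y)), transform="log")
        errs.append(abs(seg.psi - psi_true))
    assert np.median(errs) < spacing / 2


def test_continuous_mode_recovers_hinge_breakpoint_precisely():
    """With segments constrained to meet, ψ is a continuous parameter and a
    noiseless hinge is recovered to optimizer precision, not grid spacing."""
    xs = np.arange(0.2, 2.01, 0.2)
    pts = [(x, 1.0 if x < 0.9 else 1.0 + 2 * (x - 0.9)) for x in xs]
    seg = segment_breakpoint(pts, mode="continuous")
    assert seg.psi == pytest.approx(0.9, abs=1e-6)
    assert seg.left_slope == pytest.approx(0.0, abs=1e-6)
    assert seg.right_slope == pytest.approx(2.0, abs=1e-6)
    # the two segments meet at psi
    left_y = seg.left_intercept + seg.left_slope * seg.psi
    right_y = seg.right_intercept + seg.right_slope * seg.psi
    assert left_y == pytest.approx(right_y, abs=1e-6)


def test_log_transform_requires_positive_data():
    pts = [(x, 1.0) for x in range(-2, 6)]
    with pytest.raises(CalibrationError):
        segment_breakpoint(pts, transform="log")


# --- linear-range selection ----------------------------------------------

def _ratio_points(levels, ratios=None):
    return [
        RatioPoint(
            heavy_concentration=lv,
            ratio=(ratios[i] if ratios else lv / 0.015),
            replicate=1,
            heavy_area=100 * lv,
            light_area=1.5,
        )
        for i, lv in enumerate(levels)
    ]


def test_range_selection_counting():
    levels = default_broad_levels()
    points = _ratio_points(levels)
    seg = segment_breakpoint(
        [(lv, 1.0 if lv < levels[4] else lv * 7e5) for lv in levels for _ in (0, 1)],
        transform="log",
    )
    flags = [lv == levels[-1] for lv in levels]  # top level saturated
    retained, excluded = select_linear_range(points, seg, flags)
    assert len(retained) == 5
    reasons = [r for _, r in excluded]
    assert reasons.count("below_breakpoint") == 4
    assert reasons.count("saturated") == 1
    assert len(retained) + len(excluded) == len(points)


def test_no_break_no_saturation_keeps_everything():
    points = _ratio_points([0.004, 0.008, 0.016, 0.032, 0.064])
    retained, excluded = select_linear_range(points, None, None)
    assert len(retained) == 5 and not excluded


def test_too_few_survivors_instructs_redesign():
    points = _ratio_points(default_broad_levels())
    seg = segment_breakpoint(
        [(lv, 1.0 if lv < 0.2 else lv * 7e5) for lv in default_broad_levels()
         for _ in (0, 1)],
        transform="log",
    )
    with pytest.raises(CalibrationError, match="refined"):
        select_linear_range(points, seg, None)


# --- LOQ -----------------------------------------------------------------

def _curve_with_cov(slope, v00):
    fit = LineFit(
        intercept=0.0, slope=slope,
        covariance=np.array([[v00, 0.0], [0.0, 1e-6]]),
        residual_sd=math.sqrt(v00), r_squared=0.999, n=15,
    )
    pts = _ratio_points([0.004, 0.008, 0.016, 0.032, 0.064])
    return CalibrationCurve(points=pts, fit=fit, excluded=[], stage="refined")


def test_loq_from_slope_sd_formula():
    assert loq_from_slope_sd(_curve_with_cov(2.0, 0.01)) == pytest.approx(0.5)
    assert loq_from_slope_sd(_curve_with_cov(2.0, 0.0)) == 0.0


def test_loq_doubles_when_ratio_noise_doubles():
    """Residuals scale linearly into s0, so LOQ is linear in the noise."""
    x = np.repeat([0.004, 0.008, 0.016, 0.032, 0.064], 3)
    rng = np.random.default_rng(9)
    eps = rng.normal(0, 0.05, x.size)
    curves = []
    for k in (1.0, 2.0):
        y = x / 0.015 * (1 + k * eps)
        pts = [
            RatioPoint(heavy_concentration=xi, ratio=yi, replicate=1,
                       heavy_area=yi, light_area=1.0)
            for xi, yi in zip(x, y)
        ]
        curves.append(build_curve(pts, "refined"))
    s0 = [math.sqrt(c.fit.covariance[0, 0]) for c in curves]
    assert s0[1] == pytest.approx(2 * s0[0], rel=1e-9)  # residuals scale exactly
    # the slope moves slightly with the draw, so the LOQ doubles approximately
    assert loq_from_slope_sd(curves[1]) == pytest.approx(
        2 * loq_from_slope_sd(curves[0]), rel=0.1
    )


# --- inverse estimation --------------------------------------------------

def test_inverse_estimate_closed_form():
    curve = _curve_with_cov(100.0, 0.0)
    est = inverse_estimate(curve, 1.0)
    assert est.concentration == pytest.approx(0.01)
    assert est.ci95[0] <= est.concentration <= est.ci95[1]


def test_noise_free_pipeline_recovers_endogenous_exactly(panel_pair, quiet_sim):
    light, heavy = panel_pair
    endo = 0.015
    plan = SpikePlan(levels=design_refined_levels(endo).levels, replicates=3,
                     peptide=light, heavy=heavy)
    report, _ = simulate_quant_report(endo, plan, quiet_sim)
    curve, est = quantify_refined(report)
    assert est.concentration == pytest.approx(endo, rel=1e-6)
    assert not est.flags


def test_extrapolation_is_flagged():
    pts = _ratio_points([0.1, 0.2, 0.4, 0.8], ratios=[5.0, 10.0, 20.0, 40.0])
    curve = build_curve(pts, "refined")
    est = inverse_estimate(curve, 1.0)
    assert est.extrapolated
    assert "extrapolated_target_ratio" in est.flags


def test_negative_slope_rejected():
    pts = _ratio_points([0.1, 0.2, 0.4], ratios=[3.0, 2.0, 1.0])
    with pytest.raises(CalibrationError):
        build_curve(pts, "refined")


def test_fieller_and_delta_agree_for_precise_slopes(panel_pair, noisy_sim):
    light, heavy = panel_pair
    endo = 0.015
    plan = SpikePlan(levels=design_refined_levels(endo).levels, replicates=3,
                     peptide=light, heavy=heavy)
    report, _ = simulate_quant_report(endo, plan, noisy_sim)
    curve, _ = quantify_refined(report)
    delta = inverse_estimate(curve, 1.0)
    fieller = inverse_estimate(curve, 1.0, fieller=True)
    assert fieller.ci95[0] == pytest.approx(delta.ci95[0], rel=0.05)
    assert fieller.ci95[1] == pytest.approx(delta.ci95[1], rel=0.05)


# --- refined ladder design -----------------------------------------------

def test_refined_ladder_two_fold_around_estimate():
    plan = design_refined_levels(0.0125, n_levels=5, factor=2)
    assert plan.levels == pytest.approx([0.003125, 0.00625, 0.0125, 0.025, 0.05])


def test_single_level_ladder():
    assert design_refined_levels(0.02, n_levels=1).levels == [0.02]


@pytest.mark.parametrize(
    "kwargs",
    [dict(broad_estimate=-1), dict(broad_estimate=0.01, factor=1.0),
     dict(broad_estimate=0.01, n_levels=4)],
)
def test_degenerate_ladders_rejected(kwargs):
    with pytest.raises((CalibrationError, ValueError)):
        design_refined_levels(**{"n_levels": 5, "factor": 2.0, **kwargs})


# --- scale equivariance and two-stage ------------------------------------

def test_scale_equivariance_of_psi_loq_and_estimate(panel_pair):
    """Relabelling the concentration axis by k scales every concentration
    output by k and leaves ratios untouched."""
    light, heavy = panel_pair
    endo = 0.015
    k = 7.0
    plan = SpikePlan(levels=default_broad_levels(), replicates=3,
                     peptide=light, heavy=heavy)
    report, _ = simulate_quant_report(endo, plan, SimConfig(seed=13))
    scaled = report.assign(spike_level_ugml=report["spike_level_ugml"] * k)
    c1, e1 = quantify_broad(report, saturation_ceiling=1e6)
    c2, e2 = quantify_broad(scaled, saturation_ceiling=1e6)
    assert c2.segmented.psi == pytest.approx(k * c1.segmented.psi)
    assert c2.loq == pytest.approx(k * c1.loq)
    assert e2.concentration == pytest.approx(k * e1.concentration)
    assert [p.ratio for p in c2.points] == pytest.approx([p.ratio for p in c1.points])


def test_two_stage_identical_reports_give_identical_estimates(panel_pair, noisy_sim):
    light, heavy = panel_pair
    endo = 0.015
    plan = SpikePlan(levels=design_refined_levels(endo).levels, replicates=3,
                     peptide=light, heavy=heavy)
    report, _ = simulate_quant_report(endo, plan, noisy_sim)
    a = quantify_refined(report)[1].concentration
    b = quantify_refined(report.copy())[1].concentration
    assert a == b


def test_two_stage_reports_both_estimates_and_disagreement(panel_pair):
    light, heavy = panel_pair
    endo = 0.015
    broad_plan = SpikePlan(levels=default_broad_levels(), replicates=3,
                           peptide=light, heavy=heavy)
    broad_report, _ = simulate_quant_report(endo, broad_plan, SimConfig(seed=31))
    refined_plan = SpikePlan(levels=design_refined_levels(endo).levels, replicates=3,
                             peptide=light, heavy=heavy)
    refined_report, _ = simulate_quant_report(endo, refined_plan, SimConfig(seed=32))
    result = run_two_stage(broad_report, refined_report, saturation_ceiling=1e6)
    assert result.broad_estimate.stage == "broad"
    assert result.refined_estimate.stage == "refined"
    assert result.disagreement_factor >= 1.0
    assert result.broad_curve.loq is not None


def test_unbracketed_refined_ladder_is_flagged_not_fatal(panel_pair, quiet_sim):
    light, heavy = panel_pair
    endo = 0.015
    # ladder entirely above the endogenous level: all ratios > 1
    plan = SpikePlan(levels=[0.05, 0.1, 0.2], replicates=3,
                     peptide=light, heavy=heavy)
    report, _ = simulate_quant_report(endo, plan, quiet_sim)
    curve, est = quantify_refined(report)
    assert "refined_levels_do_not_bracket_ratio_1" in est.flags
    assert est.concentration == pytest.approx(endo, rel=1e-6)


def test_rt_mismatch_is_flagged_but_still_quantified(panel_pair):
    """An endogenous peptide eluting 1.9 min from its synthetic standard
    (an I/L isoform pair) still yields a calibration curve and estimate,
    with a warning routing it to sequence validation."""
    light, heavy = panel_pair
    endo = 0.015
    plan = SpikePlan(levels=design_refined_levels(endo).levels, replicates=3,
                     peptide=light, heavy=heavy)
    cfg = SimConfig(seed=51, light_rt_offset_min=1.9)
    report, _ = simulate_quant_report(endo, plan, cfg)
    curve, est = quantify_refined(report, saturation_ceiling=1e6)
    assert "heavy_light_rt_mismatch" in est.flags
    assert est.concentration == pytest.approx(endo, rel=0.1)


def test_exclusion_ledger_conserves_points(panel_pair):
    light, heavy = panel_pair
    plan = SpikePlan(levels=default_broad_levels(), replicates=3,
                     peptide=light, heavy=heavy)
    report, _ = simulate_quant_report(0.015, plan, SimConfig(seed=41))
    curve, _ = quantify_broad(report, saturation_ceiling=1e6)
    assert len(curve.points) + len(curve.excluded) == 30
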