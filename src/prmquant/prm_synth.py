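"""Seeded simulator of in-sample calibration PRM experiments.

Stands in for the LC-MS instrument plus the Skyline curation step: given an
endogenous (light) concentration and a heavy spike plan, it generates
paired light/heavy extracted-ion chromatograms with Gaussian elution peaks,
per-peptide response factors, multiplicative matrix suppression applied
equally to co-eluting light and heavy (so it cancels in the ratio — the
core rationale of the in-sample design), a hard detector saturation
ceiling, an additive noise floor, and retention times from an additive
residue model.  Everything is driven by a single seed and the ground truth
is recorded so downstream estimators can be tested for parameter recovery.

The additive noise floor is what produces the flat low-concentration
regime of a broad calibration curve (the region the segmentation analysis
has to find), and apex clipping is what bends the top of the curve below
linearity (the saturated points excluded from the fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .peak_integration import (
    REPORT_COLUMNS,
    Chromatogram,
    detect_peak,
    integrate_window,
)
from .peptide_chem import IsotopeLabel, Peptide, PrecursorTarget, precursor_mz
from .rt_validation import RetentionModel, default_retention_model, predict_rt

__all__ = [
    "SimConfig",
    "SpikePlan",
    "GroundTruth",
    "SimulatedTrace",
    "IsoformRun",
    "default_broad_levels",
    "default_heavy_form",
    "simulate_xic",
    "simulate_calibration_experiment",
    "measure_traces",
    "simulate_quant_report",
    "simulate_isoform_run",
    "simulate_piecewise_response",
    "write_quant_report",
]

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class SimConfig:
    """Instrument/simulation parameters for one experiment.

    Defaults emulate a triplicate-injection nano-LC PRM run on a 70-min
    gradient.  ``response_factor`` is peak area per (µg/mL) on column;
    ``suppression_factor`` is the matrix attenuation shared by co-eluting
    light and heavy; ``response_cv`` is a per-trace multiplicative
    coefficient of variation (channel-independent, so it does NOT cancel in
    the ratio and is what limits ratio precision); ``noise_sd`` is the
    additive intensity noise floor.
    """

    gradient_minutes: float = 70.0
    peak_fwhm: float = 0.3
    sampling_interval: float = 0.02
    response_factor: float | dict[str, float] = 1.0e6
    suppression_factor: float = 0.7
    saturation_ceiling: float = 1.0e6
    noise_sd: float = 150.0
    response_cv: float = 0.05
    replicates: int = 3
    rt_model: Optional[RetentionModel] = None
    trace_halfwidth: float = 1.2
    mz_tolerance: float = 0.1
    light_rt_offset_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_fwhm <= 0:
            raise ValueError("peak_fwhm must be positive")
        if not self.sampling_interval < self.peak_fwhm / 5:
            raise ValueError("sampling_interval must be < peak_fwhm/5")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.response_factor, dict):
            if any(v <= 0 for v in self.response_factor.values()):
                raise ValueError("response factors must be positive")
        elif self.response_factor <= 0:
            raise ValueError("response factors must be positive")
        if not 0 < self.suppression_factor <= 1:
            raise ValueError("suppression_factor must be in (0, 1]")
        if self.rt_model is None:
            self.rt_model = default_retention_model(self.gradient_minutes)

    def response_for(self, p: Peptide) -> float:
        if isinstance(self.response_factor, dict):
            key = p.residues
            if key not in self.response_factor:
                raise KeyError(f"no response factor for {key}")
            return self.response_factor[key]
        return float(self.response_factor)


@dataclass
class SpikePlan:
    """Heavy-peptidoform spike levels (µg/mL on column) for one peptide."""

    levels: Sequence[float]
    replicates: int = 3
    peptide: Optional[Peptide] = None
    heavy: Optional[Peptide] = None

    def __post_init__(self) -> None:
        levels = [float(x) for x in self.levels]
        if any(x <= 0 for x in levels):
            raise ValueError("spike levels must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("spike levels must be strictly increasing")
        self.levels = levels
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.peptide is not None and self.heavy is None:
            self.heavy = default_heavy_form(self.peptide)


def default_heavy_form(p: Peptide) -> Peptide:
    """A heavy peptidoform for ``p`` when none is specified: a
    13C(6)15N(2) label on the C-terminal residue (position is irrelevant
    for precursor m/z; fragment-level work should specify the real one)."""
    light = p.stripped()
    return Peptide(light.residues, ((len(light), IsotopeLabel(c13=6, n15=2)),))


def default_broad_levels(n: int = 10, lo: float = 1e-5, hi: float = 1.0) -> list[float]:
    """Log-spaced heavy spike ladder for a generic broad calibration curve."""
    return list(np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class SimulatedTrace:
    peptide: Peptide
    label_type: str
    spike_level: float
    replicate: int
    concentration: float
    chromatogram: Chromatogram
    true_area: float
    true_rt: float


@dataclass
class GroundTruth:
    """What the simulator actually put in: the recovery-test reference."""

    endogenous: float
    true_rt: dict[str, float]
    true_areas: list[dict] = field(default_factory=list)


@dataclass
class IsoformRun:
    """XICs of co-injected isobaric peptidoforms, one trace per m/z group."""

    chromatograms: dict[str, Chromatogram]
    true_rt: dict[str, float]


def _sigma(cfg: SimConfig) -> float:
    return cfg.peak_fwhm / _GAUSS_FWHM


def simulate_xic(
    target: PrecursorTarget,
    concentration: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    rt: Optional[float] = None,
) -> Chromatogram:
    """One Gaussian elution peak on a noisy baseline.

    True (pre-noise, pre-clipping) area is concentration × response factor
    × suppression factor, optionally jittered by a mean-one lognormal with
    CV ``response_cv``; intensities are clipped at the saturation ceiling,
    then additive Gaussian noise is applied and floored at zero.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    mu = rt if rt is not None else predict_rt(target.peptide, cfg.rt_model)
    sigma = _sigma(cfg)
    times = np.arange(
        mu - cfg.trace_halfwidth, mu + cfg.trace_halfwidth + cfg.sampling_interval / 2,
        cfg.sampling_interval,
    )
    area = concentration * cfg.response_for(target.peptide) * cfg.suppression_factor
    if cfg.response_cv > 0:
        s = math.sqrt(math.log(1.0 + cfg.response_cv**2))
        area *= rng.lognormal(mean=-0.5 * s * s, sigma=s)
    height = area / (sigma * math.sqrt(2.0 * math.pi))
    signal = height * np.exp(-0.5 * ((times - mu) / sigma) ** 2)
    signal = np.minimum(signal, cfg.saturation_ceiling)
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=times.size)
    signal = np.maximum(signal, 0.0)
    return Chromatogram(
        times=times,
        intensities=signal,
        target_mz=target.mz,
        tolerance=cfg.mz_tolerance,
    )


def _target(p: Peptide, cfg: SimConfig) -> PrecursorTarget:
    return PrecursorTarget(
        peptide=p, mz=precursor_mz(p, 1), charge=1, label_type=p.label_type
    )


def simulate_calibration_experiment(
    endogenous: float,
    plan: SpikePlan,
    cfg: SimConfig,
) -> tuple[list[SimulatedTrace], GroundTruth]:
    """Paired light/heavy chromatograms for every spike level × replicate.

    This is the reversed in-sample design: the light (endogenous) channel
    stays at ``endogenous`` across all levels while the heavy channel steps
    through the spike ladder; both co-elute and share the suppression
    factor.  A non-zero ``light_rt_offset_min`` shifts the endogenous peak
    relative to the spiked standard, emulating an I/L sequence isoform
    whose synthetic reference was built from the wrong assignment.
    """
    if plan.peptide is None:
        raise ValueError("spike plan must carry a peptide")
    light = plan.peptide.stripped()
    heavy = plan.heavy
    rng = np.random.default_rng(cfg.seed)
    rt = predict_rt(light, cfg.rt_model)  # heavy co-elutes: labels add 0
    rt_of = {
        "light": rt + cfg.light_rt_offset_min,
        "heavy": rt,
    }
    traces: list[SimulatedTrace] = []
    truth = GroundTruth(
        endogenous=endogenous,
        true_rt={
            light.to_proforma(): rt_of["light"],
            heavy.to_proforma(): rt_of["heavy"],
        },
    )
    for level in plan.levels:
        for rep in range(1, plan.replicates + 1):
            for form, conc in ((light, endogenous), (heavy, level)):
                chrom = simulate_xic(
                    _target(form, cfg), conc, cfg, rng, rt=rt_of[form.label_type]
                )
                ideal = conc * cfg.response_for(form) * cfg.suppression_factor
                traces.append(
                    SimulatedTrace(
                        peptide=form,
                        label_type=form.label_type,
                        spike_level=level,
                        replicate=rep,
                        concentration=conc,
                        chromatogram=chrom,
                        true_area=ideal,
                        true_rt=rt_of[form.label_type],
                    )
                )
                truth.true_areas.append(
                    {
                        "label_type": form.label_type,
                        "spike_level_ugml": level,
                        "replicate": rep,
                        "true_area": ideal,
                    }
                )
    return traces, truth


def measure_traces(traces: Iterable[SimulatedTrace], cfg: SimConfig) -> pd.DataFrame:
    """Integrate every trace into one quant-report row (the Skyline role).

    Peaks are detected inside the scheduled RT window.  When nothing clears
    the detection threshold the scheduled window is integrated anyway, so
    low-concentration rows report the noise floor instead of going missing
    — a broad curve needs those flat points for its segmentation.
    """
    rows = []
    half = max(3.0 * _sigma(cfg), cfg.peak_fwhm)
    for tr in traces:
        window = (tr.true_rt - half, tr.true_rt + half)
        peak = detect_peak(tr.chromatogram, expected_rt_window=window)
        if peak is not None:
            area, apex_rt, height = peak.area, peak.apex_rt, peak.height
        else:
            area, height = integrate_window(tr.chromatogram, window)
            apex_rt = tr.true_rt
        rows.append(
            {
                "peptide": tr.peptide.residues,
                "label_type": tr.label_type,
                "spike_level_ugml": tr.spike_level,
                "replicate": tr.replicate,
                "area": area,
                "apex_rt_min": apex_rt,
                "height": height,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def simulate_quant_report(
    endogenous: float, plan: SpikePlan, cfg: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """simulate_calibration_experiment + measure_traces in one call."""
    traces, truth = simulate_calibration_experiment(endogenous, plan, cfg)
    return measure_traces(traces, cfg), truth


def simulate_isoform_run(
    sequences: Sequence[Peptide],
    cfg: SimConfig,
    concentration: float = 0.05,
) -> IsoformRun:
    """Co-injection of sequence isoforms in water (no matrix): one XIC per
    precursor m/z group, with one peak per peptidoform at its model RT.

    Within each label type all peptidoforms must be isobaric (within the
    m/z tolerance); that is the point of the experiment.
    """
    if not sequences:
        raise ValueError("no peptidoforms given")
    for lt in ("light", "heavy"):
        mzs = [precursor_mz(p, 1) for p in sequences if p.label_type == lt]
        if mzs and max(mzs) - min(mzs) > cfg.mz_tolerance:
            raise ValueError(f"{lt} peptidoforms are not isobaric within tolerance")
    rng = np.random.default_rng(cfg.seed)
    rts = {p.to_proforma(): predict_rt(p, cfg.rt_model) for p in sequences}
    lo = min(rts.values()) - cfg.trace_halfwidth
    hi = max(rts.values()) + cfg.trace_halfwidth
    times = np.arange(lo, hi + cfg.sampling_interval / 2, cfg.sampling_interval)
    sigma = _sigma(cfg)
    cfg_water = replace(cfg, suppression_factor=1.0)  # water, no matrix
    chroms: dict[str, Chromatogram] = {}
    for p in sequences:
        key = f"{precursor_mz(p, 1):.2f}"
        area = concentration * cfg_water.response_for(p)
        height = area / (sigma * math.sqrt(2.0 * math.pi))
        mu = rts[p.to_proforma()]
        signal = height * np.exp(-0.5 * ((times - mu) / sigma) ** 2)
        if key in chroms:
            summed = chroms[key].intensities + signal
        else:
            summed = signal
        chroms[key] = Chromatogram(
            times=times.copy(),
            intensities=summed,
            target_mz=float(key),
            tolerance=cfg.mz_tolerance,
        )
    for key, c in chroms.items():
        noisy = c.intensities
        noisy = np.minimum(noisy, cfg.saturation_ceiling)
        if cfg.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, cfg.noise_sd, size=noisy.size)
        chroms[key] = Chromatogram(
            times=c.times,
            intensities=np.maximum(noisy, 0.0),
            target_mz=c.target_mz,
            tolerance=c.tolerance,
        )
    return IsoformRun(chromatograms=chroms, true_rt=rts)


def simulate_piecewise_response(
    levels: Sequence[float],
    psi: float,
    slope: float,
    floor: float,
    cv: float,
    replicates: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct response-level shortcut for segmentation studies: a flat noise
    floor below the breakpoint ψ and a linear rise above it, with mean-one
    lognormal multiplicative noise of the given CV.

    Returns (concentration, area) arrays with ``replicates`` draws per level.
    """
    x = np.repeat(np.asarray(levels, dtype=float), replicates)
    y_true = np.where(x < psi, floor, floor + slope * (x - psi))
    if cv > 0:
        s = math.sqrt(math.log(1.0 + cv * cv))
        y = y_true * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=x.size)
    else:
        y = y_true.copy()
    return x, y


def write_quant_report(frame: pd.DataFrame, path) -> None:
    """Write the quant-report CSV dialect (versioned by its exact header):
    ``peptide, label_type, spike_level_ugml, replicate, area, apex_rt_min,
    height``.  Numeric fields round-trip losslessly through
    peak_integration.read_quant_report."""
    missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"frame missing mandatory columns: {missing}")
    ordered = frame[REPORT_COLUMNS + [c for c in frame.columns if c not in REPORT_COLUMNS]]
    ordered.to_csv(path, index=False, float_format="%.17g")
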