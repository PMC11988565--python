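# Methods

This note documents the models, defaults and numerical choices behind
`prmquant`, and what the synthetic experiments do and do not demonstrate.

## Mass arithmetic

Peptide sequences use a deliberate subset of ProForma v2: the twenty
canonical residues, each optionally followed by one
`[Label:13C(x)15N(y)]` tag bound to the preceding residue. Monoisotopic
residue masses, water (18.010565 Da) and the proton (1.007276 Da) come
from pyteomics' NIST tables; a label adds
`x·(13.003355 − 12) + y·(15.000109 − 14.003074)` Da, so the common
13C(5)15N(1) proline label adds 6.0138 Da and the 13C(6)15N(2) lysine
label 8.0142 Da. Neutral mass and [M+H]⁺ are exposed separately —
vendor-style tables usually print the latter, and the panel's printed
"molecular weight" values are singly protonated m/z. For the heavy
`TIKIPAGT` form the package places the +8 lysine label on K3 (the label
composition is a lysine label); precursor m/z is independent of label
position, fragment m/z is not, and b/y fragment masses include a label
only when the labelled position lies inside the fragment.

Non-goals: PTMs other than isotope labels, neutral losses, isotope
envelopes.

## Simulator

`prm_synth` emulates triplicate-injection PRM runs of a spiked
hydrolysate. Per trace: a Gaussian elution peak of FWHM 0.3 min sampled
every 0.02 min (≈15 samples per FWHM) over ±1.2 min around the predicted
retention time, with true area

&nbsp;&nbsp;area = concentration × response_factor × suppression_factor,

hard-clipped at a detector ceiling (default 10⁶ counts), then additive
Gaussian noise (sd 150 counts, floored at 0). Defaults: response factor
10⁶ area/(µg/mL), suppression 0.7, a 70-min gradient. Two noise sources
matter for ratios:

* the **additive floor** dominates below ≈10⁻⁴ µg/mL and produces the
  flat low-concentration regime a broad curve's segmentation must find;
* a **per-trace multiplicative jitter** (mean-one lognormal, CV 5%)
  models injection-to-injection response variation *per channel*. A
  factor shared by the light and heavy channel of one injection would
  cancel in the ratio — matrix suppression is exactly such a factor and
  the simulator applies it identically to both peptidoforms, which is the
  design's central property and is asserted in tests (ratios are
  bit-identical across suppression 1.0/0.5/0.2 in the noise-free case).

With these defaults the 10-level broad ladder (10⁻⁵–1 µg/mL, log-spaced)
yields 2–3 noise-floor levels, one saturated top level, and a usable
linear window in between, i.e. the regime structure the two-stage method
exists for. The simulator records full ground truth (endogenous
concentration, true RTs, pre-noise areas) for recovery testing.

What the simulator does **not** model: chemical interference peaks,
LC drift, mzML-level spectra, peak tailing, and correlated run-to-run
response changes. Passing recovery tests therefore show the estimators
are correct under the stated noise model, not that real hydrolysate data
meet that model.

## Peak measurement

Peaks are detected as the intensity maximum within the scheduled RT
window; bounds extend outward until intensity drops below 1% of the apex
or a local valley below half-height (resolving adjacent isoforms); the
detection threshold is 3× a median-absolute-deviation estimate of
baseline noise; a ≥3-sample plateau at the maximum flags saturation.
Areas are trapezoidal (within 1% of the closed-form Gaussian area at ≥10
samples/FWHM, asserted against the closed form). When nothing clears the
threshold the scheduled window is integrated anyway so low spike levels
report the noise floor instead of going missing — segmentation needs
those points. No background subtraction is applied by default.
Replicates are never averaged: each injection contributes its own ratio
point so the fit sees injection-level scatter.

Every quantification also screens heavy-vs-light co-elution: a median
apex shift beyond 0.5 min sets a `heavy_light_rt_mismatch` flag on the
estimate and the CLI points the pair at the isoform-validation workflow.
The mismatch does not block quantification — an isoform pair can still
be calibrated — but the shared-matrix-effect guarantee no longer holds
exactly, and the simulator can reproduce the situation via its
`light_rt_offset_min` setting.

## Segmentation and linear range

The breakpoint ψ between noise floor and linear response is found by an
exhaustive partition search: every admissible split of the sorted points
into left/right segments (≥2 points and ≥2 distinct x each) is scored by
the summed RSS of two independently fitted lines. Because the segments
are free lines, RSS depends only on the point partition, so the sweep is
equivalent to a dense ψ grid (asserted against a brute-force oracle to
1e-6 relative RSS); ties go to the smaller ψ. Within the winning gap, ψ
is placed at the intersection of the two lines when that falls inside
the gap, else at the gap midpoint — so ψ resolution is limited by level
spacing, which is why LOQs from a shared broad ladder can coincide
across peptides. A discontinuity at ψ is allowed (the flat noise floor
and the linear segment need not meet); no continuity constraint is
imposed. An F-test (α = 0.01) against the single-line fit sets a
`no_breakpoint` flag; a perfect single line short-circuits it.

For broad curves the search runs on (log₁₀ conc, log₁₀ area): on linear
axes the top levels of a five-decade ladder dominate the RSS and the
noise floor is invisible to the search. ψ is always returned in
concentration units. Linear-range selection then drops points below ψ
(`below_breakpoint`), saturated points (`saturated`, apex at ≥99.9% of
the configured ceiling or plateau-flagged), and manual exclusions; every
input point lands in the retained or the excluded ledger, never both,
and fewer than three survivors raises an error instructing a refined
redesign.

## Calibration fit and inverse estimation

The calibration line (ratio vs heavy concentration) is ordinary least
squares on replicate-level points, unweighted (1/x weighting available).
The parameter covariance used for inference is heteroscedasticity-
consistent (HC3): area-ratio noise is multiplicative, so residual
variance grows with concentration, and the classical covariance makes
the inverse-prediction interval over-cover (empirically ≈99.6% instead
of ≈96% at nominal 95% under the simulator's 5% CV). The endogenous
concentration is the inverse prediction at ratio 1 with a delta-method
standard error and ±1.96·se interval; a Fieller interval is available
for low-precision slopes and agrees with the delta interval when the
slope is well determined. Target ratios outside the observed ratio range
set an `extrapolated` flag; estimates below the broad LOQ are flagged
`estimate_below_loq` but still reported, and a refined ladder that fails
to bracket ratio 1 is flagged, not fatal.

Two LOQ conventions: the breakpoint ψ for broad curves, and
10·s₀/slope for refined curves (s₀ = SD of the predicted ratio at x = 0
from the fit covariance). The signal-to-noise orientation is deliberate:
dividing the slope by s₀ instead would make the LOQ improve as noise
grows.

The refined ladder is geometric, `estimate · 2^k` for k = −2…+2 (five
levels), centred on the broad estimate; the broad and refined estimates
are both reported and their disagreement quantified — the refined value
is authoritative, the broad stage only designs the refined ladder.

## Retention model and I/L adjudication

Retention prediction is additive: rt = intercept + Σ coefficient(residue),
with the Guo–Mant–Parker–Hodges (1986) pH-2 coefficient set shipped as a
two-column data file. The raw coefficients are dimensionless and are
anchored to minutes using the observed apexes of one I/L isoform pair on
the 70-min gradient (22.3 / 24.2 min), i.e. one I→L substitution ≈
+1.9 min; other gradient lengths scale linearly. Only the ordering
coefficient(L) > coefficient(I) is load-bearing — it is a model
invariant — and absolute predicted minutes should not be over-read.
Isotope labels contribute nothing, so heavy/light co-elution is exact by
construction.

Adjudication toggles every I/L position (2ᵏ candidates), ranks
candidates by |predicted − observed| shift relative to the synthetic
reference, and flags consistency within a 0.5-min tolerance (half a
typical isoform separation at this gradient scale). Additive models are
compositional, so candidates related by swapping an I and an L at two
positions predict identical retention; they are reported as a tied set —
never broken arbitrarily — mirroring the fact that only a synthetic-
standard co-injection can separate them.

## Problem sizes and seeds

The stochastic studies use: 200 repetitions for breakpoint recovery
(10-level ladder, 5% CV, true ψ placed off-centre within an inter-level
gap so the midpoint convention cannot succeed by construction), 100 runs
for estimate recovery and for the broad-vs-refined comparison, and 500
runs for interval coverage — sizes at which the binomial uncertainty of
the checked rates is small against their acceptance margins while the
full suite stays fast. All simulations are driven by explicit integer
seeds (numpy `default_rng`); the CLI refuses to run without one, and
every run directory contains the resolved configuration and seed needed
to reproduce it bit-identically.

## Known limitations

* Additive retention prediction ignores sequence position effects;
  modern learned RT predictors would rank some isoform pairs that this
  model must leave tied.
* In the default free-segment mode, ψ resolution is bounded by the
  spike-level spacing. The non-default `mode="continuous"` hinge fit
  makes ψ a genuine continuous parameter, at the cost of forcing the
  noise floor and the linear segment to meet — which the data need not
  support.
* Saturation handling excludes clipped points rather than modelling the
  detector response; heavily saturated broad curves can lose their top
  levels entirely.
* The simulator's noise model is stationary; slow sensitivity drift
  between injections is not represented, so the replicate scatter seen
  in tests is a lower bound on real-world scatter.
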