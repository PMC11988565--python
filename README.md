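# prmquant

Absolute quantification of non-tryptic peptides in complex food
hydrolysates by **reversed in-sample calibration curves**, built for
targeted parallel-reaction-monitoring (PRM) mass spectrometry.

Food-grade enzymatic hydrolysis releases thousands of peptides, and the
few bioactive ones of interest sit in a matrix of co-eluting peptides,
proteins and small molecules that suppress their ionization. Spiking a
blank matrix with standards does not work — there is no blank matrix. The
approach implemented here spikes stable-isotope-labelled (heavy)
peptidoforms of each target peptide directly into the hydrolysate at a
ladder of known concentrations. The heavy copy co-elutes with the
endogenous light peptide and experiences the same ion suppression, so the
heavy/light peak-area ratio is matrix-independent, and the heavy
peptidoform serves simultaneously as calibrant and internal standard.

## The model

For a peptide with endogenous on-column concentration $c^\*$ and heavy
spike levels $x_1 < \dots < x_m$ (each injected in triplicate), the
heavy/light area ratio within the linear response range follows

$$r = \beta_0 + \beta_1 x, \qquad r = 1 \iff x = c^\*$$

and the endogenous concentration is read off by **inverse estimation** at
ratio 1: $\hat c = (1-\hat\beta_0)/\hat\beta_1$, with a first-order
(delta-method) standard error from the fit covariance (Fieller intervals
available for poorly determined slopes).

Two curve designs are chained:

1. **Broad curve** — one generic log-spaced ladder (default 10 levels,
   10⁻⁵–1 µg/mL) for all peptides. Most points fall outside the linear
   range: the low end is a flat noise floor, the top saturates the
   detector. A two-segment piecewise regression locates the breakpoint ψ
   between noise and linear response (fit on log–log axes); points below ψ
   and saturated points are excluded, ψ is the broad-curve LOQ, and the
   surviving window yields a first concentration estimate.
2. **Refined curve** — a peptide-specific five-point two-fold geometric
   ladder centred on the broad estimate. Segmentation is impossible (all
   points are linear by design), so LOQ = 10·s₀/slope with s₀ the standard
   deviation of the predicted ratio at the y-intercept. The refined
   estimate is the authoritative result.

Because isoleucine and leucine are isobaric, a mass spectrometer cannot
tell `TIKIPAGT` from `TIKLPAGT`; reversed-phase chromatography can,
because leucine is more hydrophobic. The `rt_validation` module predicts
relative retention with an additive residue-coefficient model
(Guo–Mant–Parker–Hodges 1986 set) and ranks all 2ᵏ I/L assignment
hypotheses against the observed shift between the endogenous peak and the
spiked synthetic standard. Composition-identical candidates (e.g.
`TIKLPAGT` vs `TLKIPAGT`) are reported as a tie to be broken by a
synthetic-standard co-injection.

A seeded simulator (`prm_synth`) generates the whole experiment —
Gaussian elution peaks, per-peptide response factors, shared matrix
suppression, detector saturation, an additive noise floor, and
model-derived retention times — with full ground truth, so every
estimator in the package is testable for parameter recovery.

## Worked example

```sh
prmquant demo --out demo_run --seed 1
```

```
prmquant demo (seed 1)
  HLPSYSPSP: true 0.015 | broad 0.0162 (LOQ 0.00024) | refined 0.01446 ± 0.0004 µg/mL
  HLPSYSPSPQ: true 0.021 | broad 0.0226 (LOQ 0.00024) | refined 0.02055 ± 0.0005 µg/mL
  TIKIPAGT: true 0.01 | broad 0.00999 (LOQ 0.00024) | refined 0.009922 ± 0.0002 µg/mL
  TIKIPAGT isoform check: observed shift +1.90 min → TLKIPAGT / TIKLPAGT (tie: synthetic-standard run required)
outputs in demo_run
```

Each line shows, for one peptide of the three-peptide *Vicia faba*
hydrolysate panel: the simulated endogenous truth, the broad-curve
estimate with its breakpoint LOQ, and the refined estimate with its
delta-method standard error — the refined values recover the truths to a
few percent. The last line is the I/L adjudication: the endogenous peak
elutes 1.9 min after the synthetic heavy `TIKIPAGT` standard, which is
inconsistent with the assumed sequence and consistent with the two
single-swap isoforms, exactly the situation that requires a follow-up
co-injection of synthetic isoforms. The output directory contains the
quant-report CSVs, breakpoint and calibration plots, the resolved
configuration and a log sufficient to re-run bit-identically.

The library is importable directly; the same analysis is a handful of
calls (`simulate_quant_report` → `quantify_broad` →
`design_refined_levels` → `quantify_refined`), and `simulate`,
`quantify`, `validate-isoforms` expose the stages individually on the
command line with a YAML configuration.

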