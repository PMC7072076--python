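# Methods

## The assay and its readouts

Whole blood is incubated at 37 °C with *S. aureus* bioparticles carrying
two fluorochromes: pHrodo Green, whose emission increases as the
phagolysosomal pH falls, and PF520, which is pH-insensitive and therefore
reports the number of ingested particles. Samples are acquired after 10,
20, 40 and 60 minutes of incubation. Per sample the pipeline reports:

* `phagocytosis_pct` — percentage of neutrophils whose PF520 signal
  exceeds the positivity cut;
* `mean_acid_ratio` — mean over PF520-positive neutrophils of the per-cell
  ratio pHrodo/PF520. The ratio is taken over *positive* cells only: for a
  cell that has ingested nothing the ratio is autofluorescence divided by
  autofluorescence and carries no acidification information. Both channels
  enter the ratio untransformed — the particle-number correction presumes
  linear signals;
* `mfi_pf520`, `mfi_phrodo` — mean fluorescence over PF520-positive
  neutrophils. The arithmetic mean is the primary statistic with a config
  switch for the median (`statistic="median"`), and the positive-cell
  denominator is likewise configurable.

## Gating

Gating is fully automated, with a manual mode that replays recorded
thresholds:

1. **Populations (FSC/SSC, untransformed).** A 3-component full-covariance
   Gaussian mixture is fitted to (FSC, SSC); components are assigned to
   lymphocyte / other (monocyte) / granulocyte by ascending SSC centre and
   events labeled by maximum responsibility. Initialization is k-means
   with four restarts under a fixed `random_state`, so results are
   deterministic given (data, seed). A debris floor is placed at the 0.001
   normal quantile of the lymphocyte component's FSC, using the median and
   MAD of the component's assigned events rather than the fitted scale —
   debris absorbed into the component on the first pass would otherwise
   inflate its variance and push the floor below the debris cloud. After
   removing debris the mixture is refitted on the surviving events.
2. **Neutrophils.** Among granulocytes, the CD16-positive cut (excluding
   CD16-negative eosinophils) is the deepest kernel-density valley of
   asinh-transformed CD16: a Gaussian KDE (Scott bandwidth, 512-point
   grid) is scanned for modes at least 2% of the peak density, and the cut
   is the density minimum between the leftmost and rightmost mode. This
   handles the trimodal case (eosinophil / CD16-dim / CD16-bright), where
   the widest, emptiest valley separates eosinophils from neutrophils. A
   unimodal distribution falls back to a low quantile cut (default 0.01).
3. **Subsets.** Scalar dim/bright cuts on transformed CD16 and CD62L
   (same valley rule) split neutrophils into CD16dim/CD62Lbright (banded),
   CD16bright/CD62Lbright (mature) and CD16bright/CD62Ldim (activated);
   the CD16dim/CD62Ldim quadrant is reported as unclassified and excluded
   from the three named percentages.

Marker channels use an inverse-hyperbolic-sine transform with cofactor 150
(standard for this signal range); scatter is untransformed. Events exactly
on a cut go to the bright/positive side — a fixed, testable convention.
No compensation is applied (single-laser readout) and negative stored
intensities are truncated to zero on read, with the count logged.

Auto mode re-fits thresholds per sample; all emitted cuts are recorded in
the `GatingResult` so a run can be replayed exactly in manual mode. The
marker layers replay bit-for-bit from the scalar cuts; the scatter layer
has no scalar threshold (labels come from mixture responsibilities), so
its reproducibility is carried by seed determinism instead.

PF520 positivity is decided on transformed intensity; with a negative
reference sample (e.g. an on-ice incubation) the cut is the reference's
99.5th percentile among neutrophils, otherwise the same valley rule on the
sample itself.

## Cohort statistics

* **GEE**: value ~ C(day) + group, identity link, exchangeable working
  correlation, robust sandwich errors clustered on patient (statsmodels).
  The covariate coding was genuinely open; group + categorical day is the
  simplest structure consistent with one reported coefficient per metric,
  and a group×day interaction is available as an option. A single time
  point degenerates to the two-group mean difference; a constant response
  returns beta = 0 with a degeneracy flag.
* **Per-day tests**: Mann-Whitney U, exact enumeration when the combined
  n ≤ 12 with no ties, otherwise the tie- and continuity-corrected normal
  approximation. The rank test is primary; a t-test alternative was
  considered and rejected as the cohort metrics are not normal.
* **Reference band**: mean ± t₀.₉₇₅,ₙ₋₁·SD/√n of healthy-control values —
  a stated definition of the control 95% interval rather than a silent
  one. Group means are classified above / within / below, plus a
  below-midpoint flag used for "low-normal" calls.
* **Baseline tables**: two-sided Fisher exact for 2×2 (summing
  hypergeometric probabilities ≤ the observed table's); for 2×k the
  Freeman-Halton extension by full enumeration over margin-preserving
  tables in log-factorial arithmetic, with a 1e-9 relative tolerance on
  the ≤ comparison to absorb floating-point ties.
* **Subset comparison**: classical one-way ANOVA with Tukey HSD follow-up
  on per-patient subset mean ratios at 60 min. Zero within-group variance
  with distinct means is degenerate (F unbounded; p reported 0 with a flag).
* **Screens**: Spearman rho (tie-corrected; undefined and flagged for
  constant input), Friedman chi-square for repeated temperature
  conditions (the 2-condition case reduces to a sign test), Shapiro-Wilk
  pass-through.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes, and is
the ground truth for every recovery test.

* **Scatter**: four Gaussian clusters (debris 3%, lymphocytes 27%,
  monocytes 10%, granulocytes 60%) on a 0–1000 arbitrary scale, centred so
  neighbouring leukocyte populations are ≥ 6 within-cluster SDs apart —
  clean by design, so gating failures indicate algorithmic defects, not
  ambiguous data.
* **Markers**: log-normal modes; 5% of granulocytes are CD16-negative
  eosinophils; neutrophil subsets default to 5 / 85 / 10% (banded /
  mature / activated), log-sd 0.28.
* **Uptake**: per-neutrophil particle count k ~ Poisson(λ(t, T)) with
  λ(t, T) = λmax·(1 − e^(−t/τ))·g(T), λmax = 3, τ = 25 min, and
  g(T) = 0.12 + 0.88·(T/37)^1.5 — non-decreasing in both incubation time
  and temperature, with residual uptake on ice.
* **Fluorescence**: one brightness sum per cell (log-normal per-particle
  brightness, meanlog ln 8000, sdlog 0.25) enters both channels; pHrodo is
  additionally scaled by the pH response f(pH), a decreasing logistic with
  midpoint pH 6.5, width 0.45, range [0.05, 2.2] — any strictly decreasing
  bounded curve satisfies the dye's physics; the parameters are surfaced
  in config. Both channels get independent multiplicative log-normal noise
  (sd 0.08) plus a low log-normal autofluorescence background, placed far
  below single-particle brightness so the positivity cut is recoverable.
  Because the same brightness sum drives both channels, the per-cell ratio
  is ≈ f(pH) regardless of particle count or temperature — which is what
  makes the ratio a particle-number-corrected acidification readout.
* **Phagosomal pH**: pH(t) = 7.4 − 1.6·a·(1 − e^(−t/20 min)), where the
  acidification scale a follows the (group, day) trajectory table:
  healthy 1.0 throughout; infection 1.35, 1.25 at days 0, 3 then 0.85 from
  day 6; no-infection 1.0, 1.05 early rising to 1.25–1.30 during days
  6–15. These encode the qualitative temporal pattern the cohort analysis
  must detect (early hyper-acidification in pre-infection patients, late
  elevation in the others); the magnitudes are not calibrated to any
  measured pH. Patients carry a log-normal random level (CV 8%) shared
  across their days.
* **Design**: 6 infection / 9 no-infection patients × days {0, 3, 6, 10,
  15} × incubation {10, 20, 40, 60} min plus 10 healthy controls acquired
  once — the study's group split with a generator default for the
  unreported control count. Analysis drivers and the acceptance run use
  2000 events per sample and the 60-min readout; recovery accuracy is
  unchanged from larger event counts (the convergence test checks this)
  and the full kinetics are exercised separately.

What the generator does **not** emulate: doublets, spectral spillover,
instrument drift, debris heterogeneity, inter-sample threshold drift, or
biologically overlapping populations. Passing recovery tests therefore
demonstrates correctness of the algorithms under the assay's idealized
model, not robustness to messy clinical acquisitions — the same caveat
that applies to any simulation-validated gating method.

## Numerical choices and degenerate inputs

* Mixture: `reg_covar` 1e-3, ≤ 500 EM iterations; non-convergence falls
  back to a manual polygon when provided, else errors.
* Empty inputs: a 0-event file is valid (returns an empty table); zero
  neutrophils flag percentages and metrics undefined (`None`), never 0.
* Duplicate incubation time points are an error; missing ones are flagged,
  never interpolated.
* Per-sample failures in a cohort run are quarantined and listed; the
  cohort stage proceeds on the survivors (clinical series have missing
  draws).
* All randomness flows from one integer seed: per-sample generators are
  spawned from (seed, patient index, day, incubation time), so cohorts are
  reproducible file-by-file.

## Known limitations

The dim/bright cuts are re-fitted per sample; whether fixed cross-sample
cuts would be preferable is surfaced in config rather than decided. The
absolute scale of the acidification ratio is arbitrary (no pH calibration
curve exists for the assay), so only within-cohort contrasts and
directions are meaningful. The published patient-level effect sizes are
not recoverable without the original event data; the cohort layer is
validated by estimator calibration and by reproducing the direction of
the temporal pattern.
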