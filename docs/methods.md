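# Methods

`nanobiopsy` models the computational side of a double-barrel nanopipette
platform for longitudinal single-cell cytoplasmic sampling: the barrel
electrics, the ion-current traces the instrument records, the detectors
that turn those traces into quality-control decisions and extracted-volume
estimates, a lineage Monte-Carlo for the feasibility of re-sampling the
same cell days later, and the downstream single-cell expression pipeline
that classifies proneural (PN) versus mesenchymal (MES) glioblastoma
phenotypes and tests for treatment-dependent subtype switching. Everything
is testable against synthetic data generated by the package itself.

## Barrel electrical model (`sicm_model`)

Each barrel is a truncated hollow cone of electrolyte with tip radius
`r_tip` (default 75 nm, reading the ~150 nm pore as a diameter), half-cone
tangent `taper` and filled length `L` (default 5 mm; it only enters through
the back radius). The series resistance is the exact integral of the
conical resistor, `R = L / (pi kappa r_tip r_back)`. Conductivities:
aqueous 1.30 S/m, organic 0.01 S/m (a Methods-level source also quotes
0.011; 0.01 is the default and both are accepted through configuration),
cytoplasm 0.35–0.5 S/m with 0.425 as the point default.

The measured median barrel resistances (45.7 MOhm aqueous, 2.7 GOhm
organic, ratio 59) are not consistent with a single shared geometry and
the conductivity ratio of 130, so each barrel is calibrated independently:
`calibrate_taper` inverts the closed form for the taper that reproduces a
target resistance. This treats the published medians as medians over
pipettes rather than properties of one cone.

Near a surface the current follows `i(z) = V / (R + alpha/z)`; the access
coefficient `alpha` is fixed operationally so the magnitude falls to the
scanning set point (99.5% of baseline) at a configurable set-point
distance (default 100 nm), because the platform uses the set-point drop
operationally rather than a specific access-resistance formula.

After electrowetting draws a cytoplasm column of length `ell` into the
organic barrel, the barrel is two conical resistors in series; the
resistance is strictly decreasing in `ell` whenever the cytoplasm conducts
better than the organic phase, so `invert_ingress` can recover `ell` from
a resistance by bisection (absolute tolerance 1 nm). The extracted volume
is the conical frustum of length `ell`, reported in femtoliters.

## Trace simulator (`trace_sim`)

Traces are sampled at 10 kHz. The injection trace is piecewise:

1. **Approach** — continuous descent at 10 nm/ms along the access curve.
   The feedback halts when the current falls to 99.5% of the *measured*
   baseline (the median over its first 50 ms window) — not of the true
   far-field value, which a trace that stops exactly at the set point
   would never cross — and keeps moving for a 3-ms latency before the
   halt, as instrument feedback does. The ground-truth `hop_stop` is the
   set-point crossing sample.
2. **Hop retract** by 2 um, bias switch to the injection potential.
3. **Stepped descent** in 100-nm steps (10 ms motion + 40 ms dwell).
   Above the cell the current follows the true access curve; during the
   descent the access distance is floored at the set-point distance — the
   soft membrane deflects ahead of genuine contact and does not seal
   after it — so the only sharp feature at the membrane is the touch
   step: an instantaneous fractional drop (default 2%).
4. **Vibrational noise** switches on within 300 nm of the substrate:
   band-limited Gaussian noise (brick-wall 50–500 Hz, 50 pA RMS). The
   true spectrum of this disturbance is not published; the band and
   amplitude are stand-ins, and the detectors are validated against the
   simulator's own band.
5. **Substrate contact**: the current is exactly zero until a 100-nm
   retraction, followed by the injection hold.

White Gaussian noise (default 10 pA sd, a typical 10-kHz patch-clamp
floor against the ~4.4 nA aqueous baseline) is added throughout. The
membrane height defaults to the median indentation of the glial-cell
preset (5.06 um; an epithelial preset at 3.32 um is provided).

The extraction trace holds at +300 mV, switches to −500 mV for 10 s, and
holds again. During extraction the ingress grows as
`ell(t) = ell_max (1 − e^(−t/tau))` (tau default 1.5 s) and the moving
liquid–liquid interface contributes `sign(V) * beta * d ell/dt` to the
current — the simplest dynamics reproducing the published trace shape
(fast at first, decaying). `calibrate_extraction_example` solves the
empty-barrel taper from the pre-extraction hold current, the ingress from
the post-extraction hold, and `beta` from the switch-on peak, so the
printed worked example (0.35 nA → −2.83 nA peak → 0.70 nA) is reproduced
by construction. After the switch-back the column is pinned at
`ell_max`.

## Detectors (`phase_detect`)

A successful membrane penetration shows three subphases in order —
hopping stop, membrane touch, vibrational noise — and the QC verdict is
exactly that conjunction. Numerical choices:

- *Sustained* conditions must hold 10 consecutive samples (1 ms) to
  reject spikes.
- **Hop stop**: first crossing of the smoothed magnitude (51-sample
  centred average; the approach slope near the set point is shallow, so
  wide smoothing buys noise rejection without biasing the crossing)
  below `0.995 x` the first-window median baseline.
- **Membrane touch**: step-aligned — dwell levels are medians over the
  constant-position segments from the z channel, and a touch is the
  first dwell whose level falls below `touch_fraction x` the previous
  dwell's level, refined to the first below-threshold sample. The
  default `touch_fraction` is 0.985, midway between baseline and the
  expected 2% drop: a threshold placed exactly at the post-drop level
  (0.98) is undecidable under noise, with half the samples on each side.
  Without a position channel a trailing-window median is used instead.
- **Vibration onset**: a causal 3rd-order Butterworth bandpass (no
  energy leaks backwards across the onset), then a three-stage
  estimate on the in-band power `x`: (i) an L2 change point
  (maximising `t(n−t)(mean_l−mean_r)^2`) establishes presence — the
  post/pre power ratio must clear `vib_ratio_threshold` (default 8) —
  and the two power levels; (ii) a penalised maximum-likelihood change
  point for exponentially distributed power locates the onset, with the
  per-sample penalty scaled by a quarter of the power decorrelation
  length so correlated quiet-floor excursions cannot pull it early and
  in-band lulls cannot push it late; (iii) the onset snaps to the first
  sample above 15x the quiet floor near the ML estimate, minus the
  filter's deterministic 10% energy-rise latency. On the simulator's
  default band this is exact to ±2 samples noise-free and places all
  three subphases within ±20 samples on ≥95% of noisy traces; the
  residual jitter is at the information limit a 50–500 Hz band allows.
- **Substrate contact / retraction**: raw magnitude at or below /
  above `contact_floor` (default 3x the robust noise sd estimated from
  first differences, since "zero current" is only meaningful relative
  to noise).

`measure_delta_i` medians the two hold segments of the organic trace
(excluding 0.5-s settling margins located from the bias pattern) and
reports `delta_i = |post| − |pre|`.

## Volume estimation (`extraction_volume`)

`estimate_volume` converts the two hold currents into resistances,
inverts the plug model, and reports the frustum volume together with the
full assumption record and an uncertainty interval from re-evaluating at
cytoplasm conductivities 0.35 and 0.5 S/m. The estimate is qualitative
by design — access resistance during the hold reads is neglected and the
true estimator coefficients are not recoverable — so a zero or negative
current change yields a flagged zero-volume estimate rather than an
error. Cohort summaries report order statistics of `delta_i` and volume
and the fraction at or below a threshold (default 200 fl).

## Recapture Monte-Carlo (`recapture`)

A founder cell starts at the centre of the 1300 x 1300 um field of view.
Per 2-h step each living cell takes a 2-D random-walk step (half-normal
length, scale `speed_scale x` step, uniform direction); division and
death compete as exponential clocks (the divider keeps its identity and
spawns a daughter in place). Defaults are calibrated to the published
anchors, which are explicitly calibration targets rather than acceptance
values: division ln2/24 per h (a 24-h doubling, so three rounds and ~8
cells over 72 h), death 0.04 per h (~17% lineage survival at 72 h,
matching the ~18–25% survival of biopsied cells) and speed scale
35 um/h (the founder ever leaves the field of view in ~1–2% of runs and
its maximum displacement stays below 800 um, as observed). The day-4
biopsy picks uniformly among surviving in-field cells because the
platform cannot tell the founder from progeny; replicates with no
survivor are excluded from the conditional denominator and reported.
With three forced division rounds the recapture probability is 1/8,
consistent with the published ~14% estimate. Note that under *any*
exchangeable death process the conditional pick probability stays
exactly 1/8 by symmetry — death does not raise it — and with
age-dependent exposure it is marginally below.

## Expression pipeline (`transcriptomics`)

The pipeline starts from a genes x cells counts matrix with
protein-coding / mitochondrial / ribosomal flags. Alignment-level
metrics are proxied at the counts level: "% ribosomal bases" by the
ribosomal-protein-gene count fraction and "% mRNA bases" by
`100 − %mito − %ribo`, unless an external per-cell table is supplied.

Steps, with strict inequalities exactly as stated for the platform:
cells need >150 expressed protein-coding genes, <10% ribosomal and <30%
mitochondrial counts; genes need >3 counts in ≥2 cells and a
protein-coding flag; depth normalisation to 10,000 counts then log1p;
per-gene OLS residuals on the per-cell covariates (expressed genes and
the %mRNA proxy for nanobiopsies), dropping collinear columns; per-gene
z-scores clipped from above at +5; top-600 highly variable genes by the
dispersion method (variance/mean z-scored within 20 equal-frequency
mean bins, ties broken lexicographically by gene id); PCA on the scaled
HVG matrix with 8 components, component signs fixed by making the
largest-magnitude loading positive.

Per-cell phenotype scores use a single-sample rank-walk enrichment
statistic (a GSVA-style surrogate; the original kernel-based statistic
belongs to other work): genes are ranked by scaled expression, the walk
gains `|stat| / sum(|stat| over the set)` at set genes and loses
`1/(N − n_set)` elsewhere, and the score is the signed maximum
deviation, bounded in [−1, 1]. A cell is PN or MES by the larger score;
exact ties are unclassified. Paired day-1/day-4 labels give the 2x2
switch table (pairs with an unclassified member are excluded and
counted; incomplete pairs are reported), tested with a two-sided Fisher
exact test (scipy's conditional exact test; the test suite checks it
against full enumeration in rational arithmetic on every 2x2 table with
total ≤ 20). On the published 7/10-vs-1/9 switch table the two-sided
exact p is 0.0198; the printed 0.0094 cannot be reconciled with the
standard two-sided, one-sided or mid-p constructions and is documented
as such rather than targeted. Plasticity is summarised as the
untreated/treated ratio of mean absolute score changes with Welch
t-tests.

A UMAP-style 2-D embedding is deliberately left out: the analysis-grade
quantities (scores, labels, switch table) depend only on the PCA space,
and embedding internals are treated as pluggable plumbing.

## Synthetic counts (`synth_expression`)

Counts are negative-binomial (overdispersion 0.5) around a fixed
relative-expression profile: log-normal baseline shares, mitochondrial
and ribosomal blocks rescaled to the capture profile's target fractions
(23.4% mito for nanobiopsies, 7.5% for whole cells; 5% ribo), and two
50-gene PN/MES modules at moderately high baseline. A phenotype
multiplies its module's shares by `e^effect` (default effect 2.0,
~7-fold — in line with strong subtype markers) and the boost is
renormalised within the non-mito/ribo block so the technical fractions
stay at target. Capture depth is calibrated per phenotype profile so
the expected expressed-gene count hits the profile target (497
protein-coding genes for nanobiopsies, 1100 for whole cells) regardless
of the planted biology — the generator's technical covariates are
independent of phenotype by construction, which is what a technical
null should look like. Per-cell log-normal jitter on capture
efficiency (sd 0.1) and on the mitochondrial load (sd 0.4) produces a
realistic spread, including cells that fail the 30%-mito filter.

`gen_paired_cohort` plants day-1 phenotypes uniformly and flips day-4
phenotypes with the arm's switch probability (0.7 untreated, 0.11
treated, n = 10/9 pairs), returning the planted truth. It also
generates ~100 unpaired day-1 biopsies, mirroring the real design in
which the longitudinal samples are normalised, regressed and scaled
jointly with the much larger day-1 cohort: running the per-gene
covariate regression on the paired subset alone lets chance
phenotype–covariate correlation absorb module signal and flip
covariate-outlier cells, a leverage effect that disappears at the real
cohort size.

What the generator does *not* emulate: gene-length and GC biases,
doublets, batch effects, ambient contamination, or any real marker-gene
identities (the gene sets are synthetic labels). Passing tests
therefore show that the pipeline arithmetic, thresholds, scoring and
test statistics behave as specified on data with the documented
moment structure — not that the platform's biological conclusions
replicate.

## Problem sizes and determinism

Every stochastic component takes a seed and is bit-reproducible.
Simulation sizes used by the test suite and the acceptance script were
chosen to make the Monte-Carlo standard errors small against the
tolerances they are checked with: 200 injection traces for detector
recovery, 10,000 replicates for the three-division recapture limit,
2,000 for the out-of-field probability, 40 paired cohorts (138 cells
each) for the end-to-end switch recovery, and 600 lineages for the
branching-expectation check (with a 0.25-h step so the discrete-time
expectation `(2 − e^(−lambda dt))^(t/dt)` sits within 1.5% of the
continuous `e^(lambda t)`).

## Known limitations

- The access-resistance form `alpha/z`, the exponential ingress, the
  instantaneous touch drop and the vibration band are phenomenological;
  they reproduce published landmarks, not device physics.
- The volume estimate inherits every caveat of the plug model and is
  best read as an order of magnitude; the published claim it supports
  is itself qualitative ("less than a picoliter").
- Detector timing tolerances are tied to the simulator's noise model; a
  different vibration spectrum would need re-validation (the band and
  thresholds are configurable).
- The recapture model has no contact inhibition, no treatment-dependent
  motility and uncorrelated division/death across a lineage.
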