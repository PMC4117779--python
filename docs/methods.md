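# Methods

This note documents the models, parameter choices and numerical conventions
behind `telquant`, and what the synthetic-data tests do and do not
demonstrate.

## Unit conventions

All conversions run through `telquant.units`. Radioactivity uses the exact
definition 1 μCi = 2.22 × 10⁶ dpm; scintillation cpm are converted to dpm by
a counting efficiency that defaults to 1.0 (instrument-specific, rarely
reported with bench recipes) and is configurable everywhere a cpm enters.
RNA molar mass is `length × 320.5 Da + 159 Da`, the standard calculator
convention for a 5′-triphosphate/3′-OH in-vitro transcript. The hTR length
is fixed at the canonical 451 nt; with these constants 2 pg of hTR converts
to 8.32 × 10⁶ molecules, matching the printed figure for the northern
detection limit to within 0.3%. Optional first-order decay corrections are
provided for ³⁵S (t½ 87.4 d) and ³²P (t½ 14.26 d) but are off by default:
for material counted within days of labeling they change results by a few
percent at most, and whether the original measurements applied them is
unknown.

## Spike-in RT-qPCR estimator

The estimand is endogenous target copies per cell. The design titrates `S`
molecules of synthetic standard into total RNA from a counted number of
cells before reverse transcription. Because standard and endogenous
molecules then share RT efficiency, primer-annealing environment and PCR
efficiency, the reference-normalized quantity of a spiked sample divided by
its matched unspiked sample estimates `1 + S/E` where `E` is the endogenous
amount per reaction. The calculated ratio `R = Q_spiked/Q_unspiked − 1` is
therefore linear through the origin in `S` with slope `1/E`.

Choices:

- **Through-origin fit by default.** It makes the ratio-equals-one reading
  rule exact (`R = 1 ⇔ S = E`). An unconstrained fit is available; it reads
  `E` where the fitted line crosses `R = 1`.
- **Weighting.** Unweighted by default; optional `1/S` weights emphasize the
  low-spike points nearest the crossing.
- **Negative ratios are retained.** Under Cq noise, `R ≤ 0` can occur at
  small spikes; truncating them would bias `E` upward. They are flagged in
  the fit report.
- **Cq replicates** are averaged per sample; groups with a range above 0.5
  cycles are flagged (a common qPCR QC convention).
- **Efficiency correction.** Per-primer efficiency from a dilution series
  (`E = 10^(−1/slope)`, requiring ≥3 points spanning ≥2 logs) when
  available, else perfect doubling (2.0). The estimator is invariant to the
  reference gene's absolute level; only its stability across the titration
  matters.

## Blot quantification

Calibration is a least-squares line of band signal on standard molecules,
origin-forced by default (zero molecules ⇒ zero net signal after background
subtraction; a free intercept is available). Inputs are net densitometry
values — image analysis and background subtraction are upstream. Samples
whose signals fall outside the standards' range are converted but flagged
`extrapolated`, never suppressed. For doublet-running targets the two band
signals should be summed per lane before entry. Detection-limit bounds are
the faintest detectable standard divided by cells loaded, reported as an
upper bound. Internal-control normalization (e.g. H1 RNA, β-actin) is
provided as an explicit function but not applied implicitly: whether the
original blot quantifications normalized to the control or used it only as
a QC check is not documented, so QC-only is the default posture.

## ³⁵S protein standard

Molecules of in-vitro translated protein follow from mass balance on the
methionine pool. The default recipe supplements an RRL reaction with 10 μl
of 1.0 mM cold Met (10 000 pmol) and 10 μl of a 1 mCi/98 μl, 1175 Ci/mmol
³⁵S-Met stock (102.04 μCi ≈ 86.8 pmol), giving a pool specific activity of
≈2.246 × 10⁴ dpm/pmol. Endogenous lysate methionine is negligible relative
to the supplement (validated in the original characterization of this
system) and defaults to zero; an additive term is exposed for sensitivity
analysis, and at 1% of the supplement it moves estimates by ≤1%.
Protein-band purity (the fraction of counted radioactivity actually in the
product band) defaults to 0.9. The methionine count per protein molecule is
deliberately a required parameter — it depends on the exact tagged
construct — with a FASTA-counting helper.

## IP mass balance

The assembled-monomer estimator
`N_RNP = N_hTR (1 − r_hTR)/(1 − r_act)` rests on three assumptions: all
telomerase activity resides in assembled RNP; hTR is depleted by the
anti-protein IP only as part of assembled RNP; and both depletions scale
with the same pull-down efficiency, which cancels. `r_act = 1` (no activity
depleted) is an estimation error. `r_hTR < r_act` implies an assembled
fraction above 1; this is physically impossible but reachable under noise,
so it yields a flagged estimate rather than an exception, and the free-pool
arithmetic floors at zero with a flag.

The hTERT estimator multiplies `N_RNP` by the elution hTERT:hTR molar
ratio, assuming the IP antibody captures free and assembled hTERT with equal
affinity. The alternative reading — that the elution protein band
under-counts because a large free-hTERT pool escapes the IP — is exposed in
the simulator as the `pull_free_tert` switch rather than as a reporting
default.

Replicate aggregation is mean ± sample SD (n−1). Per-replicate
reproductions from published two-significant-figure ratio tables agree with
the published per-replicate estimates to within ~6% (the rounding of the
inputs), and replicate means to within ~2%; these tolerances are encoded in
the acceptance tests.

## Direct assay

The dGTP pool of the standard recipe is 500 pmol cold (20 μl × 25 μM) plus
10 pmol hot (30 μCi at 3000 Ci/mmol) in 50 μl — 10.2 μM total, specific
activity 1.306 × 10⁵ dpm/pmol. Product radioactivity is gel signal relative
to the 18-mer loading control times the LC's counted cpm times the fraction
of LC radioactivity in the 18-mer band (default 0.9); the gel's arbitrary
exposure scale cancels in the ratio. Total nucleotides are dGMP
incorporations divided by the asymptotic G fraction of the repeat (0.5 for
TTAGGG); no correction is made for the first, permuted repeat on the
primer, an error below 5% for products of two or more repeats. Specific
activity divides nucleotide molecules by enzymes in the reaction and
minutes; the enzyme count is the elution hTR measurement (hTR in an
anti-hTERT IP elution counts telomerase monomers), scaled by the fraction
of the elution assayed, which cancels against the products and leaves the
result fraction-invariant. Linearity validation fits an origin-forced line
to time-course or enzyme-titration series and flags points deviating more
than 15% (configurable).

## Kinetics

The Lineweaver–Burk fit is ordinary least squares of 1/v on 1/S; Vmax =
1/intercept, Km = slope/intercept, with SDs by the delta method from the
coefficient covariance. The covariance uses the HC3
heteroscedasticity-robust estimator: the reciprocal transform concentrates
noise in the low-velocity points, and with nonrobust covariance the ±2 SD
intervals undercover (≈78% at 5% multiplicative noise in our simulations,
vs ≥93% with HC3). A w ∝ v⁴ weighted variant is also provided. The
nonlinear fit minimizes squared error on `v = Vmax·S/(Km+S)` directly
(scipy `curve_fit`, initialized from the Lineweaver–Burk estimates,
parameter tolerance 1e-10); the two agree exactly on noiseless data, and
the nonlinear fit is the less biased on low-S-heavy designs. Technical
replicates are averaged per concentration before fitting; biological
replicates are fit separately and summarized as mean ± SD.

## Synthetic-data generator

The generator emulates the *measurement process*, not telomerase biology:

- **qPCR**: `Cq = baseline − log_E(copies) + N(0, σ_cq)`, with matched
  spiked/unspiked samples sharing cells and reference level. σ_cq defaults
  to 0.15 cycles.
- **Blot**: `signal = k × molecules × LogNormal(0, σ)` with a per-gel scale
  `k`; σ defaults to 0.1 (multiplicative, matching imaging practice).
- **IP**: bead-bound = ε × assembled pool (optionally + ε × free protein);
  flow-through = input − bound exactly before noise, so conservation holds
  by construction; measured counts optionally Poisson.
- **Direct assay**: expected product counts run through the same dGTP-pool
  forward model the analysis inverts, with Poisson counting; velocity is
  Michaelis–Menten-limited at the recipe's dGTP concentration.
- **Assembly**: the equilibrium model treats per-cell counts as
  concentrations in an implicit fixed volume, so Kd is in molecules/cell;
  the assembled count is the smaller root of
  `x² − (A+B+Kd)x + AB = 0`, computed in the numerically stable form
  `2AB/(s + √(s² − 4AB))`.

Scenario presets pin the study conditions: `hek293t_like` (800 hTR, 280
hTERT, 240 RNP per cell), `hela_like` (1300, 500, 240), `va13_like`
(telomerase-negative, zero hTR) and `super_telomerase` (hTR ×60 within the
measured 40–90× range, hTERT ×10, re-assembled with the Kd ≈ 93
molecules/cell implied by the baseline inventory). Default noise magnitudes
are conventional bench values, not measured ones.

What passing recovery tests shows: the estimators invert their own
generative models without bias at the stated noise levels, the IP estimator
really is pull-down-efficiency-free, and the arithmetic chain from recipes
to per-cell counts is self-consistent. What it does not show: robustness to
systematic effects absent from the generator — RNA extraction losses,
RT efficiency differences between a naked standard transcript and
protein-bound cellular RNA, antibody affinity differences between free and
assembled protein, chemiluminescence nonlinearity, and gel-to-gel transfer
variation. Those are exactly the caveats that apply to the laboratory
numbers as well.

## Problem sizes and tolerances

Simulation-based checks use 40–200 seeds per grid point (200 for the
headline spike-in and kinetics recoveries, 50–120 elsewhere), chosen so the
Monte-Carlo standard error is comfortably below each asserted tolerance.
Numerical identities are asserted at 1e-9 relative; parameter-recovery
medians at 5–10% depending on the noise level; reproductions of published
values at the rounding precision of their printed inputs (see IP section).

## Known limitations

- The spike-in ratio reconstruction `R = spiked/unspiked − 1` and the
  ³⁵S mass-balance formula reproduce the published anchor numbers but the
  original supplementary derivations were not available; both are modeling
  reconstructions.
- Error propagation within a single replicate is delta-method only; no
  bootstrap over wells/lanes.
- Band-level gel analysis (ladders, processivity) is out of scope; the
  direct-assay interface takes a single summed product signal.
- The equilibrium assembly model is a deliberately minimal formalization of
  a qualitative mass-action argument; it ignores biogenesis, degradation
  and cell-cycle dynamics.
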