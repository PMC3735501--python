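# Methods

## Experimental layout modelled

Equine PBMCs are incubated with or without 1 µg/ml LPS and with one of four
carbohydrate supplements — GOS alone, GOS/FOS (9:1), GOS/FOS/AOS (9:1:2), or
glucose/lactose controls matched to the sugar content of the GOS syrup — at
total oligosaccharide concentrations of 0.5, 1 and 2% w/v, plus blank and
LPS-alone references: 26 conditions in all.  Outcomes are TNF-α and IL-10 in
culture supernatant (ELISA, pg/ml) and CCK-8 cell viability relative to
blank.  Five horses contribute the oligosaccharide arm, four the
glucose/lactose control arm (both arms share blank and LPS-alone
references), three the viability arm; each (horse, condition) is run in
triplicate (quadruplicate supported).

Dose covariates are the % w/v of each oligosaccharide *component*, not the
nominal mixture strength: "GOS/FOS/AOS 2%" carries 1.5% GOS, 0.167% FOS and
0.333% AOS.  This lets one random slope per component express horse-specific
reactivity to each named exposure, and gives sugar controls the same
random-effect structure with zero oligosaccharide entries.

## Formulation arithmetic

Product mass for a target oligosaccharide mass is `target / oligo_fraction`;
each co-carried component contributes `product mass × fraction`.  Nominal
product compositions (GOS syrup 45/14/16/25, FOS 96.5/3.5, AOS
85.5/7.25/7.25) are used because they reproduce the published per-10-ml
composition table exactly at 2-decimal half-up rounding.  Blend targets are
expressed as oligosaccharide masses per 10 ml (9:1 and 9:1:2 of 200 mg
total at 2%); maltodextrin and monomers are tracked but excluded from the
oligosaccharide total.  Dilution divides every mass by the factor; factors
below 1 are rejected.

Endotoxin activities measured in 1% solutions are extrapolated linearly with
solids concentration.  The EU→ng conversion deliberately reproduces the
source convention `(EU/ml × 5, EU/ml × 10)` derived from the LPS potency
statement "1 ng = 5–10 EU", although a strict unit reading of "EU per ng"
would divide: the multiplicative form is what the reported ranges follow
(1.92 EU/ml ↔ 9.6–19.2 ng/ml), and this module's job is to reproduce that
reported arithmetic, not to re-derive assay dosimetry.  Standard-deviation
propagation through the extrapolation is out of scope (only scaled point
values are reported downstream).

## The hierarchical model

Per analyte, on the natural-log scale:

* likelihood: `log y_i ~ N(β_{c(i)} + z_iᵀ b_{h(i)}, σ²)` with cell-means
  fixed effects (one β per condition) and
  `z = (1, 1{LPS}, GOS%, FOS%, AOS%)`;
* random effects: `b_h ~ MVN(0, Σ_b)` — intercept (general reactivity) and
  four exposure slopes per horse;
* priors: `β_j ~ N(0, 100²)`; `σ² ~ Inv-Gamma(shape 2.0001, scale 1.0001)`,
  i.e. mean 1 and variance 10,000 via `shape = 2 + m²/v`,
  `scale = m(shape−1)`; `Σ_b` scaled inverse-Wishart.

Cell means rather than additive dose effects: all reported quantities are
per-condition estimates and condition-pair ratios, and the GOS/FOS/AOS
dose–response is non-monotone, which an additive dose model cannot express.
Analytes are modelled separately; nothing in the reported analysis involves
cross-analyte correlation.  LPS enters the random-effect design as a
presence indicator since only 0 and 1 µg/ml occur.

The scaled inverse-Wishart is the parameter-expanded construction
`Σ_b = diag(ξ) Ω diag(ξ)` with `Ω ~ IW(I₅, df 6)` (dimension + 1, giving
uniform marginal correlations) and independent `ξ_k ~ N(0, 100²)` — so the
implied scale `|ξ_k|` is half-normal and the sign of ξ is unidentified but
irrelevant (Σ_b and b = diag(ξ)η are sign-invariant).  The named prior
family fixes no hyperparameters; the scale matrix I₅, df 6 and the ξ scale
are declared package defaults, configurable through `PriorSpec`.

Wells below the detection limit (15.625 pg/ml TNF-α, 156.25 pg/ml IL-10)
contribute through latent log values bounded above by the log limit (data
augmentation).  With no censored wells the augmentation step is an exact
structural no-op.

## Gibbs sampler

Every full conditional is closed-form, so the sampler is pure Gibbs:
independent normals for β (the cell-means X makes X′X diagonal), one
5-dimensional MVN per horse for the expanded effects η (batched Cholesky
across horses), scalar normals for each ξ_k, inverse-gamma for σ²,
inverse-Wishart for Ω (Bartlett decomposition; the Wishart draw is kept as
Ω⁻¹ for the next sweep), and upper-truncated normals for censored latents
(inverse-CDF via `scipy.special.ndtr/ndtri`, with an exponential tail
approximation when the truncation probability underflows).

Protocol: four chains, 1,000,000 iterations each, every 50th kept, first
half discarded (the full profile); a desk-scale profile of 4 × 20,000 with
thinning 10 is the default for tests and examples and mixes to max R̂ ≈ 1.03
on default synthetic data.  Chains differ only in a deterministic substream
of the master seed and in overdispersed starts: β at observed cell means
plus N(0, 1) jitter (posterior SDs are ~0.1, so starts are strongly
overdispersed), σ² log-jittered around the residual variance, η standard
normal, ξ ~ N(1, 0.5²).  Convergence is the classical (non-split)
Gelman–Rubin potential scale reduction factor computed on the saved draws,
`R̂ = sqrt(((n−1)/n·W + B/n)/W)`, for every monitored parameter (all β, σ²,
the Σ_b diagonal), with pass threshold 1.1 — the threshold is a declared
convention, as the original protocol reports none.

Monitored correctness properties (all in the test suite): exact agreement
with the closed-form conjugate posterior on a fixed-effects model with known
variance; agreement to ~0.004 on the log scale with a brute-force 2-D grid
integration of the exact censored-likelihood posterior; prior recovery with
empty data; seed determinism; initialisation insensitivity across master
seeds.

## Reporting

Point estimate = posterior median of `exp(β_j)`; interval = 2.5/97.5%
percentiles, computed on the log scale and exponentiated so that bounds
commute exactly with the back-transformation (the median is used because it
commutes with monotone maps; whether the original analysis used mean or
median is not stated).  Contrasts are per-draw ratios of exponentiated cell
means; the integer percent change is computed from the (1-decimal) summary
point estimates, mirroring how the published percentages round from the
published tables; significance = the ratio interval excludes 1, with no
further multiplicity adjustment.  Viability is reported relative to blank,
with a "significant increase" flag when the lower bound exceeds 1.  Report
tables mark conditions `*` against their reference (blank when unchallenged,
LPS-alone when challenged) and `#` against the next-lower dose of the same
fraction.

Two of the sixteen quantified percentages in the source text do not
reproduce from the printed tables by integer rounding (13,793% vs
recomputed 13,784%; 53% vs 54%) — consistent with rounding from unrounded
posteriors; the contrast engine recomputes from its own inputs and the tests
document both exceptions.

## Synthetic-data generator

The raw plates are not public, so the generator *defines* the study
conditions rather than estimating them.  Condition log-means are anchored to
the published per-condition point estimates (blank TNF-α 12.6 pg/ml,
LPS-alone 1749.4, the non-monotone triple-blend response, IL-10 flat at
~185 pg/ml in unchallenged cells).  Quantities never printed as absolute
values are derived from the printed relative effects: sugar-control TNF-α
from the +53/97/84% blank contrasts and the LPS-challenged +24%/+42% dose
steps above a 1.15× non-significant offset (chosen so the 2% triple blend
vs its matched control reproduces the −71% figure); sugar-control IL-10 at
120 pg/ml, below the 156.25 detection limit, matching "mostly below
detection"; viability multipliers 1.38/1.50/1.61 for the triple blend
(spanning the reported 38–61% range monotonically) and 1.14 for the
mid-dose sugar control.

Noise scales are synthetic calibration choices, not recovered truth:
well-level SD σ = 0.4 and diagonal Σ_b with SDs (0.25, 0.30, 0.10, 0.30,
0.20) for (intercept, LPS, GOS, FOS, AOS per % w/v), chosen so simulated
95% intervals have widths comparable to the published tables; viability
uses σ = 0.10 with small random effects.  Each (horse, analyte) pair draws
from a substream keyed by identifier, so adding a horse never perturbs
existing horses' wells.

A consequence worth noting: the blank TNF-α anchor (12.6 pg/ml) lies below
the TNF-α detection limit (both values are as reported), so most synthetic
blank TNF-α wells are censored and the blank cell mean is only weakly
identified — its credible interval is bound-and-prior dominated.  The
replicated-calibration study therefore aggregates coverage across all 26
conditions (~95–97% observed); per-condition coverage for the nearly fully
censored conditions can be below nominal, which is a property of the design,
not of the sampler.

What passing tests on synthetic data do *not* show: recovery of the actual
study's numbers (the published tables are used only as fixed inputs to the
contrast engine), robustness to plate spatial effects, pipetting error
structure, or ELISA standard-curve nonlinearity — none of which the
generator emulates.

## Problem sizes and numerical choices

Default test and acceptance fits use the desk-scale profile (4 × 20,000,
thin 10, ~400 wells, ~15 s per fit); the calibration study runs 20
replications in `scripts/acceptance.py` (520 coverage trials, binomial SE
≈ 1%) and 8 in the test suite.  Percent changes round half away from zero;
reported masses round half up to 2 decimals; summaries round to 1 decimal
(2 for viability ratios).  Degenerate inputs fail loudly: empty plate
files, conditions missing from the catalogue, non-PSD covariances,
zero-draw chain configurations, non-positive values without a censoring
flag, and W = 0 in the PSRF all raise descriptive errors.

## Known limitations

* The sampler is single-threaded and the full 4 × 1,000,000 protocol takes
  hours at desk scale; the desk profile is statistically adequate for the
  synthetic studies here.
* The generator's between-horse covariance is diagonal by default; real
  horses likely correlate intercepts and slopes.  The model estimates a full
  Σ_b regardless.
* Viability is modelled on the log scale like the cytokines, which treats
  the blank-relative ratio as a log-scale difference; absorbance noise is
  approximately multiplicative in the relevant range, but this is an
  assumption, not a fit.
* `build_report`'s marker conventions assume the standard condition label
  grammar; custom catalogues with other label formats get summaries but no
  reference marks.
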