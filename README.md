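# oligopbmc

Bayesian hierarchical analysis of oligosaccharide immunomodulation in
LPS-challenged equine peripheral blood mononuclear cells (PBMCs).

Dietary oligosaccharides — galacto-oligosaccharides (GOS), long-chain
fructo-oligosaccharides (FOS) and pectin-derived acidic oligosaccharides
(AOS) — modulate immune responses, but commercial preparations are impure
(the GOS syrup is roughly 45% GOS, 14% glucose, 16% lactose, 25% water) and
carry traces of endotoxin, so any *in vitro* dose–response analysis has to
track the co-administered sugars, the endotoxin load, and strong
between-animal variation in PBMC reactivity.  This package implements the
full desk side of such a study for equine PBMCs challenged with 1 µg/ml LPS
and supplemented with GOS, 9:1 GOS/FOS or 9:1:2 GOS/FOS/AOS at 0.5–2% w/v:

* **formulation** — incubation-mixture arithmetic (product mass needed for a
  target oligosaccharide mass, co-carried glucose/lactose/maltodextrin/
  monomers, serial dilution) and Limulus-assay endotoxin extrapolation and
  EU→ng conversion;
* **study_data** — the condition catalogue, plate-well data model with
  left-censoring at the ELISA detection limits (15.625 pg/ml TNF-α,
  156.25 pg/ml IL-10), and CSV I/O;
* **synthetic_data** — a generator producing plate datasets with the same
  hierarchical anatomy (the raw study plates were never published);
* **hier_model / mcmc** — the Bayesian hierarchical linear regression and a
  self-contained conjugate Gibbs sampler with Gelman–Rubin diagnostics;
* **inference** — condition summaries, 95% credible intervals, percent-change
  contrasts and significance flags.

## The model

For each analyte (TNF-α, IL-10, cell viability) separately, with wells *i*,
horses *h(i)* and conditions *c(i)*:

```
log y_i | β, b, σ²  ~  N( β_{c(i)} + z_iᵀ b_{h(i)}, σ² )
b_h                 ~  MVN( 0, Σ_b ),          h = 1…H
β_j                 ~  N( 0, 100² )
σ²                  ~  Inv-Gamma(mean 1, variance 10,000)
Σ_b                 ~  scaled inverse-Wishart( I₅, df 6 )
```

The fixed effects are cell means (one coefficient per condition); the
random-effect design `z = (1, 1{LPS}, GOS%, FOS%, AOS%)` gives each horse a
random intercept (general PBMC reactivity) and random slopes for its
reactivity to LPS and to each oligosaccharide.  Wells below the detection
limit enter by data augmentation as upper-truncated latent values.  The
scaled inverse-Wishart is implemented by parameter expansion
(`Σ_b = diag(ξ)·Ω·diag(ξ)`, `Ω ~ IW(I₅, 6)`, ξ ~ broad normal), keeping every
full conditional conjugate, so posterior simulation is a pure Gibbs cycle.
Condition estimates are posterior medians of `exp(β_j)` with 2.5/97.5%
percentile bounds; a contrast is significant when the 95% interval of the
condition ratio excludes 1.

## Worked example

```python
from oligopbmc import *
from oligopbmc.mcmc import check_convergence

design = default_study_design()                  # 5 + 4 + 3 horses
params = default_generative_params(seed=42)      # anchored condition means
wells = simulate_dataset(design, params)
print(f"simulated {len(wells)} wells "
      f"({sum(w.below_detection for w in wells)} below detection)")

dm = build_design(wells, design.conditions, analyte="TNFa")
data = extract_observations(wells, "TNFa")
draws = run_chains(dm, data, PriorSpec(), MCMCConfig(scaled_down=True, seed=0))
conv = check_convergence(draws)
print(f"max PSRF {max(conv.psrf.values()):.3f} (pass: {conv.passed})")
for lab in ("blank", "LPS", "LPS + GOS/FOS/AOS 2.0%"):
    s = summarize_condition(draws, lab)
    print(f"{lab:28s} {s.point_estimate:8.1f} ({s.lower:.1f}-{s.upper:.1f})")
c = compare(draws, "LPS + GOS/FOS/AOS 2.0%", "LPS")
print(f"GOS/FOS/AOS 2% vs LPS alone: {c.percent_change:+d}% "
      f"(ratio BCI {c.ratio_bci[0]:.2f}-{c.ratio_bci[1]:.2f}, "
      f"significant: {c.significant})")
```

prints (desk-scale profile, 4 chains × 20,000 iterations, thin 10):

```
simulated 792 wells (162 below detection)
max PSRF 1.007 (pass: True)
blank                            11.7 (7.8-16.8)
LPS                            1685.3 (1067.0-2584.7)
LPS + GOS/FOS/AOS 2.0%          975.8 (487.3-1963.7)
GOS/FOS/AOS 2% vs LPS alone: -42% (ratio BCI 0.33-1.01, significant: False)
```

The fit recovers the generating structure: unchallenged PBMCs produce ~12
pg/ml TNF-α, the LPS challenge induces a ~140-fold response, and the 2%
triple oligosaccharide blend suppresses it by roughly 40% — here with a
ratio interval just touching 1, so a single simulated five-horse study does
not always declare that suppression significant.

A command-line interface wraps the same pipeline:

```sh
oligopbmc formulate                       # per-10-ml composition table
oligopbmc simulate --seed 1 --out plate.csv --truth-out truth.json
oligopbmc fit plate.csv --analyte TNFa --out draws.npz --convergence-out conv.json
oligopbmc report draws.npz --summary-out summary.csv --report-out report.json
```

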