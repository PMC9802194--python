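# Methods

This note documents the models, the default parameter choices and their
rationale, what the synthetic generator does and does not emulate, the
numerical choices, and known limitations.

## Porewater solute model

The column is a 1-D cell-centred finite-volume grid, depth `x` in cm
positive downward from the sediment–water interface, porosity `φ` per
cell.  One solute obeys

    ∂(φC)/∂t = ∂/∂x( φ D_s ∂C/∂x ) + φ [α_P(x) + α_B(x)] (C_ow − C) + φ (R − kC)

* `D_s = D₀ / (1 − 2 ln φ)` — Boudreau's tortuosity correction, the
  standard choice for sands.  `D₀` defaults: DIC 1.0, sulfate 0.48
  cm²/day (free-solution values near 15 °C).
* Nonlocal exchange `α(x)(C_ow − C)` swaps porewater directly with the
  water column at rate `α` (1/day), the canonical representation of both
  wave/tide pumping and burrow flushing.  Shapes:
  `α_P(x) = a_P·exp(−x/L_P)` (surface-intensified physical pumping) and
  `α_B(x) = a_B` on a window `[z1, z2]` with half-cosine edges (the
  burrow/feeding zone).  Few parameters, qualitatively matching
  surface-decaying physical mixing and subsurface irrigation.
* `R` is an optional constant-with-depth production (mineralization DIC
  source; negative for sulfate consumption).  It is off in the plain
  solver and **on in the synthetic geochemistry scenario**: from
  homogenized (uniform `C = C_ow`) initial conditions the equation has
  `C ≡ C_ow` as a fixed point, so without a reaction term the exchange
  rates would be unidentifiable.  `k` is a first-order-sink hook used by
  the analytic solver checks.
* Boundaries: fixed `C = C_ow` at the interface (tidal flushing pins
  it), zero-gradient at 40 cm (profiles flatten at depth).  No-flux and
  fixed-value variants exist for both ends; closed-column runs drive the
  conservation audits, and a fixed-value bottom makes the semi-infinite
  `C₀·e^(−x√(k/D))` oracle exact on a finite column.
* Burial/advection is neglected (weeks-scale experiments; sedimentation
  negligible).

Time stepping is backward Euler in diffusion, exchange and reaction —
unconditionally stable, exactly mass-conservative, monotone.  Because
the spatial operator is symmetric and constant within a run, the
implicit iterate is advanced in its generalized eigenbasis: identical
results to the step-by-step tridiagonal solve (to roundoff) at a
fraction of the cost, which keeps the 50-replicate recovery studies
cheap.  Default step: `dt ≤ 0.1/max(rate)`.

## Solid-phase pigment model

Chlorophyll *a* (per g wet sediment) is deposited at the surface as a
flux, mixed by Fickian biodiffusion `D_P(x) + D_B(x)` (same
amplitude-times-shape forms as the exchange rates), and decays at
`k_chl`; pheopigment receives `yield·k_chl·Chl` and decays at `k_pheo`.
The decay chain (yield 1.0, `k_pheo = k_chl/10`) is a modelling choice —
fresh pigment degrades to pheopigment much faster than pheopigment is
lost.  The chl→pheo coupling is stepped explicitly (first order in dt);
everything else implicitly.  Calibration uses the steady state (a direct
tridiagonal solve): pigment profiles reflect a seasonal balance, unlike
the weeks-scale porewater transients.

Defaults: `k_chl = 0.05/day` (≈ 2-week pigment half-life), surface flux
1 µg cm⁻² day⁻¹, `d_P = 2 cm²/day` with 4 cm e-folding (wave-worked
surface sand), `d_B = 0.5 cm²/day` over 5–20 cm (deposit-feeder
reworking at natural density).

## Calibration

Least squares on log concentrations: residuals are ln(model) − ln(obs)
with the model linearly interpolated from cell centres to observation
depths.  Concentration errors are multiplicative, so the log scale is
the matched weighting — every observation contributes its relative
error, analytes on different scales (DIC ~2–9 mM, sulfate ~28 mM)
combine without variance bookkeeping, and the informative
near-equilibrium surface observations are not drowned out by the large
absolute noise of high-concentration deep samples (plain per-analyte
inverse-variance weighting roughly triples the spread of the recovered
exchange amplitudes).  Optimizer: bounded Powell search from 8
seeded Latin-hypercube starts; best loss wins, exact ties broken by the
lexicographically smallest parameter vector; identical data + seed give
identical results.  Attribution follows the experimental design:

1. `fit_physical_porewater` — defaunated data, `α_B ≡ 0`, fits
   `(a_P, L_P)`.
2. `fit_bioirrigation` — refaunated data, `α_P` frozen at stage-1
   estimates, fits `(a_B, z1, z2)` with `z2 = z1 + width` to keep the
   window ordered.  Adding the biological term can only decrease the
   minimized loss (nested models).
3. `fit_particle_mixing` — stage 1 fits `(d_P, L_DP)` on nonbioturbated
   pigments; stage 2 freezes them and fits the `d_B` amplitude over the
   configured window.  The window is not co-fitted: a steady-state
   profile constrains the amplitude well but its edges only weakly, and
   the recovery target is `d_B`.

Porewater fits are transient from uniform initial conditions equal to
the overlying-water value (plots were sieved and homogenized at T0) and
use the first two time points (day 14 and 28).  DIC and sulfate share
the exchange parameters and are fitted jointly.

## Synthetic world

The generator's defaults are the stated world of the package's tests:

* Geochemistry: `a_P = 0.3/day, L_P = 4 cm`; `a_B = 0.15/day` over
  8–18 cm; DIC production 0.25 mM/day and sulfate consumption
  0.125 mM/day (2:1 sulfate-reduction stoichiometry; DIC reaches
  ≈ 9 mM by day 28 at depth, typical of organic-rich intertidal
  porewaters).  Observations: 15 depths (1–29 cm), T1/T2 (day 14/28),
  replicates I–III, 5% multiplicative log-normal noise.  Noise streams
  are keyed by (analyte, time point, replicate) but not by treatment,
  so a scenario with `a_B = 0` produces bit-identical defaunated and
  refaunated observations at the same seed.  The bioirrigation
  amplitude sits deliberately in the regime `R/α_B` comparable to
  several noise standard deviations; much larger amplitudes pin the
  window to `C_ow` and only a lower bound on `α` would be identifiable.
* Pigments/grain size: steady pigment profiles per treatment from the
  forward model; sand fraction 0.72 ± 0.02 (additive Gaussian, clipped
  to [0, 1]) with a +0.2 bump over 15–25 cm in the bioturbated column —
  the planted feeding signal.
* Communities: three domains (bacterial/archaeal 16S, eukaryotic 18S),
  4 classes each of "surface", "subsurface" and "neutral" roles, 6
  ZOTUs per class.  Surface classes decline logistically with depth
  (midpoint 10 cm), subsurface classes mirror them.  Classes of one
  role share a log-normal latent factor (SD 1.0 vs independent noise
  SD 0.4) — the planted correlation clusters — and the factors are
  shared across domains, planting interdomain dependence.  Reads are
  multinomial at 15–25k per sample.  The biologically impacted layer
  (12.5–25 cm) of the bioturbated arm carries a planted depletion:
  qPCR totals ÷100 (prokaryotes) and ÷10 (eukaryotes), and a random
  half of ZOTUs suppressed ×0.02, producing the richness loss.
  Trees are random coalescent-style topologies with exponential branch
  lengths — valid for UniFrac, no attempt at realistic phylogeny.

What a green end-to-end test establishes: the pipeline detects planted
layer depletions, recovers planted clusters and locates the planted
feeding window *under this generative model* — log-normal noise,
multinomial sampling, logistic depth responses.  It does not establish
robustness to compositional artefacts, PCR/primer bias, overdispersed
sequencing noise, spatial autocorrelation between pseudo-replicated
depths, or real phylogenetic structure.

## Community statistics

* Rarefaction: multivariate hypergeometric draw (without replacement),
  default depth 90% of the smallest sample total; samples below depth
  are dropped.  Richness defaults to a single seeded draw (replicate
  averaging available by looping seeds).
* UniFrac: weighted-normalized `Σ b|A−B| / Σ b(A+B)` (bounded [0, 1]) and
  unweighted `Σ b·XOR / Σ b·OR` over branch-wise descendant fractions.
* PCoA: eigendecomposition of the double-centred Gower matrix; negative
  eigenvalues reported, excluded from variance proportions, no
  Lingoes/Cailliez correction by default.
* PERMANOVA: Anderson's pseudo-F from the squared-distance partition,
  free label permutations (no strata), `p = (1 + #{F* ≥ F}) / (1 + N)`.
* CAP: retain leading PCoA axes covering ≥ 95% of positive-eigenvalue
  variance (or user-set `m`); least-squares projection of retained
  coordinates onto the standardized environment; constrained axes from
  the SVD of the fitted values.  Explained proportions are relative to
  the *total* positive-eigenvalue variance, so constraining on PCo1
  returns exactly PCo1's share.  Variables are pre-filtered by a
  marginal distance-based (McArdle–Anderson) permutation test at
  P < 0.05.
* Spearman networks: Pearson correlation of mid-ranks; two-sided p from
  the t-approximation for n ≥ 10, permutation for n < 10; significance
  mask at p < 0.05 with no multiple-testing correction (the number of
  tests is recorded on the result).  Clusters: average-linkage on
  1 − ρ; automatic k maximizes mean within- minus between-cluster ρ
  over k ∈ [2, 8].
* Distance correlation: Székely's sample dcor from doubly-centred
  Euclidean distance matrices.  Significance is a permutation test
  (resampling sample labels of one block), the validity-preserving
  reading of a "bootstrap" null; a percentile bootstrap CI is available
  behind a flag.

## Numerical choices and degenerate inputs

* Zone boundaries (12.5, 25 cm) are half-open, lower-inclusive of the
  deeper zone, consistent with "> 25 cm" phrasing for the undisturbed
  layer.
* Welch's t with two zero-variance groups: t = 0, p = 1 if the means
  agree, else ±∞ with p = 0.
* freshness index and gene ratios return NaN (missing), not errors, at
  zero denominators; functional fractions ≥ 100% are flagged, not
  clipped.
* Zero-variance classes are excluded from networks (recorded on the
  result); constant observation sets make exchange amplitudes
  unidentifiable and return the lower bound with a warning flag.
* Optimizer tolerance `xtol` defaults to 1e-7 (noiseless
  self-consistency to ~1e-4); the recovery harness accepts the default.

## Limitations

* 1-D, burrow-averaged: no burrow-resolving 2-D/3-D geometry, no
  tidal-cycle forcing, no temperature dependence.
* The exchange/biodiffusion functional forms are declared shapes, not
  inferred mechanistically; fitted amplitudes are conditional on them.
* No formal uncertainty quantification beyond the replicate harness; no
  compositionality correction in the networks (plain Spearman on
  relative abundances by design).
* δ¹³C source apportionment and raw-read processing are out of scope:
  the pipeline starts at profiles and ZOTU tables.
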