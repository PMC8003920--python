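# Methods

## Carbamylation kinetics

Carbamates inhibit cholinesterases covalently: the inhibitor QC binds the
enzyme E in a reversible Michaelis-type complex (dissociation constant
`K_a`, mol/L) which decays into the carbamylated enzyme EC with the
first-order rate `k_max` (1/min). At a fixed inhibitor concentration the
loss of activity is pseudo first-order,

    v_i(t) = v_0 · exp(−k_obs t),        k_obs([QC]) = k_max [QC] / (K_a + [QC]),

and the overall second-order inhibition rate constant — the potency measure —
is `k_i = k_max / K_a` (L mol⁻¹ min⁻¹). When `[QC] ≪ K_a` the hyperbola is
indistinguishable from the line `k_obs = k_i [QC]` and only `k_i` is
identifiable.

**Estimation.** `fit_kobs` regresses `ln(v_0/v_i)` on incubation time
through the origin (the model has no intercept; an intercept flag exists for
diagnostics). `v_0` comes from inhibitor-free control probes. Points with
`v_i ≤ 0` cannot be log-transformed and are dropped and counted.
`fit_concentration_dependence` fits both the through-origin line and the
saturation hyperbola; the hyperbola is adopted only when all three hold:

1. the extra-sum-of-squares F-test rejects the line at α = 0.05 (1 extra
   parameter, n − 2 residual df);
2. the nonlinear fit converged; and
3. the fitted `K_a` is below 5× the largest tested concentration — an
   identifiability guard: a `K_a` far beyond the tested range cannot be
   distinguished from a straight line, so such compounds are reported in
   linear mode with `k_i` only.

The saturation fit is damped least squares (`scipy.optimize.curve_fit`,
Levenberg–Marquardt) on log-parameterised `(k_max, K_a)`, which enforces
positivity; initial values are `k_max = 1.2 · max(k_obs)` and `K_a` set to
the concentration interpolated at half the largest `k_obs`; relative
tolerances 1e-10. Confidence intervals are asymptotic t-based at 95% from
the Jacobian at the optimum; the `k_i = k_max/K_a` interval uses exact
first-order propagation in log-parameters (`var log k_i = var log k_max +
var log K_a − 2 cov`). An optional flag weights the concentration fit by
the `k_obs` standard errors; unweighted is the default since assay
protocols rarely report the weighting.

Decarbamylation is deliberately neglected in fitting (it is much slower
than the assay timescale); the simulator exposes `k_decarb` so robustness
to that assumption can be probed. With `k_decarb > 0` the simulator uses
the closed-form solution of the two-state linear ODE
`a' = −k_obs a + k_decarb (1 − a)`, which relaxes to the equilibrium active
fraction instead of zero; the test suite cross-checks it against numerical
integration.

**Selectivity.** `selectivity_table` reports `k_i(BChE)/k_i(AChE)` per
compound; a ratio near 1 marks a dual, non-selective inhibitor.

## Fingerprint chemometrics

The bioactivity model regresses a response (by default `log10 K_a`, since
dissociation constants span orders of magnitude; an identity transform is
available) on principal-component scores of a compound × energy-variable
matrix.

**NIPALS PCA.** Components are extracted sequentially by power iteration on
the residual matrix: start from the column of largest variance, alternate
`p = Xᵀt/tᵀt` (normalised) and `t = Xp` until the relative change of the
score vector falls below 1e-9 (max 1000 iterations), then deflate
`X ← X − t pᵀ`. PCA is run on the covariance structure (columns are
mean-centred, not scaled). Component signs are fixed so the
largest-magnitude loading element is positive. The algorithm is fully
deterministic. Two components are retained by default (the scree of the
study-like synthetic matrices flattens after two); this is configurable.

**Polynomial regression.** The design matrix holds every monomial in the
retained scores up to a total degree 1–5 — intercept, pure powers and cross
terms, in graded lexicographic order (`--pure-powers`-style restriction is
available through building the design by hand). Coefficients solve
`B = (XᵀX)⁻¹XᵀY` through an SVD pseudo-inverse with singular values below
1e-12 of the largest treated as zero; at full rank this equals the
normal-equations solution, otherwise the minimum-norm solution is returned
with a warning.

**Validation and selection.** Leave-one-out cross-validation refits the
regression n times; we report the mean squared prediction error (`cv_mse`),
`q² = 1 − PRESS/TSS`, and the mean of the fold training R² values
(`avg_r2_loo`). The last two answer different questions — predictive skill
versus training-fit stability — and are deliberately printed side by side,
never conflated. `select_model` chooses the degree with the smallest
`cv_mse` among admissible degrees (those with `#terms ≤ n − 2`, which
excludes saturated fits: with 13 compounds and 2 scores, degrees 4–5 have
15–21 terms and are unfittable); ties break toward the lower degree.

PCA and column centering are computed once on the full matrix and LOO is
applied to the regression stage only, mirroring the two-stage workflow the
model emulates. This leaks a small amount of held-out information through
the scores; a fold-wise variant (recompute centering + PCA inside each
fold) is the conservative alternative and is easy to compose from the
library functions.

## CNS/BBB descriptor screen

Passive blood–brain-barrier permeation is screened with strict upper
bounds recommended for CNS-active drugs: MW < 450 g/mol, logP < 5, HBD < 3,
HBA < 7, RB < 8, PSA < 70 Å². Lower bounds exist in the literature only
qualitatively and ship disabled; they can be enabled per descriptor.
Missing descriptors yield status `unknown` and are excluded from the
verdict with a warning. The radar export divides each descriptor by its
upper bound, so 1.0 marks the edge of the favourable region.

Descriptor conventions (all computed with RDKit on the drawn species —
quaternary ammonium salts are profiled as the cation, with counterion
stripping logged):

- **MW** — from the molecular formula using a pinned table of IUPAC
  conventional atomic weights (shipped as a versioned CSV), so elemental
  percentages and weights are bit-reproducible.
- **PSA** — Ertl topological PSA. One deliberate adjustment: RDKit scores
  the charge-separated nitro representation `[N+](=O)[O−]` at 43.14 Å²,
  while Ertl's published fragment value for the neutral pentavalent form
  `N(=O)=O` is 45.82 Å², which is what mainstream descriptor platforms
  report. The backend adds the 2.68 Å² difference per nitro group so nitro
  compounds score in the neutral-form convention.
- **HBD** — donor hydrogens (each N–H/O–H hydrogen counts 1), the dominant
  platform convention; a donor-group count is switchable.
- **HBA** — N + O atoms, excluding quaternary positively-charged nitrogen
  (no lone pair to accept).
- **RB** — RDKit's strict rotatable-bond definition (non-ring single bonds
  between heavy atoms, terminal and amide-type bonds excluded).
- **logP** — not reimplemented (no public algorithm to reproduce):
  delegated to RDKit's Crippen atom-contribution estimator by default, or
  taken from a supplied table; provenance is recorded per field either way.

Elemental analysis percentages are rounded half-up to two decimals, the
printed convention of CHN reports; unrounded values are available and sum
to 100 within 1e-9.

## Synthetic data

The generators exist because the study's raw assay time courses and
molecular-dynamics energy matrices are not publicly deposited; they emulate
the statistical structure the analysis assumes, which is what makes the
round-trip and oracle tests meaningful.

**Assay panels** (`generate_panel`): per compound, `k_i` is sampled
log-uniformly inside the observed per-enzyme envelope (AChE (1.0–15)×10³,
BChE (1.5–24)×10³ L mol⁻¹ min⁻¹) and `K_a` log-uniformly in 10–200 µM
(log-uniform because both constants span decades); `k_max = k_i · K_a`.
The design grid is 6 log-spaced concentrations in 2–200 µM (inside the
0.5–200 µM assay range) × 6 incubation times 0–20 min. Velocity noise is
multiplicative log-normal with a mean of exactly 1 and a default CV of 3%,
typical spectrophotometric repeatability.

**Energy fingerprints** (`generate_fingerprints`): a rank-2 signal
`s₁p₁ᵀ + s₂p₂ᵀ` with orthonormal loading directions (QR of a Gaussian
matrix), score sds (4, 2.5), plus i.i.d. Gaussian noise of sd 0.3, at the
default size 13 compounds × 60 variables. With these defaults the expected
two-component share of total variance is ≈ 22.25/(22.25 + 60·0.09) ≈ 0.80;
at n = 13 the sampled share fluctuates roughly between 0.70 and 0.92. The
planted response is the cubic `0.8 z₁³ − 1.2 z₁z₂ + z₂²` in the
standardised scores (a linear variant exists for diagnostics), plus
Gaussian noise of sd 10% of the response sd.

**What the synthetic data does not emulate:** correlated (non-i.i.d.)
energy variables, heteroscedastic or drifting assay noise, substrate
competition and chromophore kinetics in the activity readout, and any real
structure–activity link between the 13 fixture compounds and the planted
response. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not field performance on wet-lab data.

**Compound fixture** (`paper_compounds`): the 13 quinuclidine carbamates
with names, printed molecular formulas where the source gives them,
name-derived formulas otherwise, and curated SMILES. The printed formula of
compound 13 is inconsistent with its 3-chlorobenzyl name (no Cl, one extra
CH₂); both formulas are carried, flagged. SMILES for compounds 1, 2 and 11
are inferred from the naming conventions and flagged as such.

## Problem sizes and determinism

Every stochastic test and the acceptance script run from explicit seeds.
The recovery benchmarks use 13-compound panels over 20 seeds (kinetics) and
40-compound fingerprint sets over 20 seeds (model selection) — sizes chosen
so each benchmark completes in seconds while the medians and modal choices
are stable across reruns.

## Known limitations

- Saturation-mode confidence intervals are asymptotic; at 5–6
  concentrations they are approximate and can undercover.
- The F-test model discrimination assumes i.i.d. Gaussian residuals on the
  `k_obs` scale; strong weighting violations shift its size.
- The leakage caveat of full-matrix PCA under LOO (above).
- Crippen logP differs from proprietary platform estimates by up to ~1 log
  unit for charged species; rule verdicts near the logP bound should be
  read with that in mind.
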