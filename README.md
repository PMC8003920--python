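# quincarb

Analysis pipeline for quinuclidine carbamate cholinesterase inhibitors:
covalent inhibition kinetics, fingerprint chemometrics, and a CNS
drug-likeness screen.

Carbamates inactivate acetylcholinesterase (AChE) and butyrylcholinesterase
(BChE) by carbamylating the active-site serine. The package is built for
medicinal chemists and enzyme kineticists who need to turn time-dependent
inhibition assays into rate constants, relate those constants to molecular
fingerprints, and judge whether candidate inhibitors can reach the central
nervous system.

## What it computes

**Kinetics.** At inhibitor concentration [QC], residual activity decays as
v_i(t) = v₀·exp(−k_obs·t) with

    k_obs = k_max·[QC] / (K_a + [QC]),        k_i = k_max / K_a,

where K_a is the dissociation constant of the reversible enzyme–inhibitor
complex, k_max the maximal carbamylation rate, and k_i the overall
second-order inhibition rate constant (the potency measure,
L·mol⁻¹·min⁻¹). k_obs is estimated per concentration from through-origin
regressions of ln(v₀/v_i) on t; the concentration dependence is classified
as linear or saturating by an extra-sum-of-squares F-test with an
identifiability guard on K_a. BChE/AChE ratios of k_i quantify selectivity.

**Chemometrics.** A compound × energy-variable matrix is mean-centred and
decomposed by NIPALS PCA (X = Σ tᵢpᵢᵀ, extracted by power iteration with
deflation). The retained scores feed polynomial regressions
(full monomial basis up to total degree 5, coefficients via
B = (XᵀX)⁻¹XᵀY solved by SVD pseudo-inverse), validated by leave-one-out
cross-validation; the degree minimising the LOO mean squared prediction
error is selected, with q² = 1 − PRESS/TSS reported alongside.

**CNS screen.** Six descriptors against the recommended ranges for
CNS-active drugs — MW < 450 g/mol, logP < 5, HBD < 3, HBA < 7, RB < 8,
PSA < 70 Å² — computed from structure with RDKit (Ertl TPSA, Crippen logP)
or supplied as a table, plus exact molecular-formula arithmetic (molecular
weight and CHN elemental percentages from a pinned IUPAC atomic-weight
table).

**Synthetic data.** Seeded generators emulate the assay panels
(exponential decay, saturating k_obs, multiplicative noise) and the
fingerprint matrices (low-rank-plus-noise with a planted polynomial
response), so the whole pipeline is testable without proprietary data.

## Worked example

```python
import numpy as np
from quincarb import kinetics as K
from quincarb.synthetic import DEFAULT_DESIGN

params = K.SchemeParams(k_max=0.12, K_a=4e-5)   # k_i = 3000 /M/min
series = K.simulate_activity(params, DEFAULT_DESIGN, v0=1.0,
                             noise_cv=0.03, seed=7)
pairs = [(s.qc_conc, K.fit_kobs(s)) for s in series]
fit = K.fit_concentration_dependence(pairs)
print(fit.mode, round(fit.k_max, 4), round(fit.K_a * 1e6, 1),
      round(fit.k_i, 1))
```

prints

```
saturation 0.1198 38.5 3114.8
```

— the saturating concentration dependence was detected and the true
constants (k_max 0.12 min⁻¹, K_a 40 µM, k_i 3000 M⁻¹min⁻¹) recovered to a
few percent under 3% assay noise.

The same workflow from the shell:

```
quincarb simulate panel --seed 3 --out sim/
quincarb kinetics --in sim/activity.csv --out results/
quincarb bbb --paper-compounds --out results/
```

The screen of the 13 in-study compounds prints `pass` for every compound
except the 4-nitrobenzyl salt (compound 4), which fails on PSA alone
(75.36 Å² against the < 70 Å² bound) — the nitro group adds 45.82 Å² of
polar surface on top of the carbamate's 29.54 Å².

## Layout

- `src/quincarb/kinetics.py` — simulation and fitting of carbamylation kinetics
- `src/quincarb/chemometrics.py` — NIPALS PCA, polynomial regression, LOO
- `src/quincarb/formulas.py` / `cns.py` — formula arithmetic and the BBB screen
- `src/quincarb/synthetic.py` — seeded generators and the 13-compound fixture
- `src/quincarb/pipeline.py` / `cli.py` — orchestration, config, `quincarb` CLI
- `docs/methods.md` — model assumptions, conventions, and limitations
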