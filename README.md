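# nsh2kit

Conformational-state and free-energy analysis for two-state allosteric SH2
domains, built around the machinery used to establish the alpha/beta
allosteric model of the SHP2 N-SH2 domain.

The N-SH2 domain of the tyrosine phosphatase SHP2 populates two
conformations: an **alpha state** (closed pY loop, spread Y-shaped central
beta-sheet, closed +5 site) that activates SHP2, and a **beta state** (open
pY loop, closed parallel beta-sheet, open +5 site) that stabilizes the
autoinhibited protein. Which state a bound phosphopeptide selects — largely
through the residue it places in the +5 pocket — decides whether binding
activates the enzyme. `nsh2kit` implements, as a tested and reusable
library, the computational pipeline behind that model:

- **Conformational-state analysis** — least-squares (Kabsch) superposition
  on the rigid domain core, essential-dynamics PCA of the backbone
  covariance matrix, subvectors of the dominant mode restricted to the
  pY loop (Ser34–Phe41) and the +5 site (Gln57–Glu97), three order
  parameters (Lys35 Cα–Thr42 Cα, Gly39 C–Asn58 N, Tyr66 Cα–Leu88 Cα),
  Pearson coupling analysis, and quadrant classification into
  alpha / beta / mixed with Wilson confidence intervals.
- **GROMOS conformational clustering** — greedy neighbor-count clustering on
  a pairwise-RMSD matrix, automatic cutoff from the first mode of the RMSD
  distribution, and umbrella-window seed selection from a pulling trace.
- **Umbrella sampling / WHAM** — self-consistent solution of

  p_j = Σᵢ n_ij / Σᵢ Nᵢ exp[β(Fᵢ − wᵢ(ξ_j))],  Fᵢ = −k_BT ln Σ_j p_j exp[−β wᵢ(ξ_j)]

  with per-bin errors from the Bayesian bootstrap of complete histograms.
- **Crooks-theorem free energies** — the Bennett acceptance ratio (the
  maximum-likelihood estimator under P_F(W)/P_R(−W) = exp[β(W − ΔG)]), the
  density-crossing diagnostic, bootstrap errors, and thermodynamic-cycle
  ΔΔG composition (positive ΔΔG = augmented preference for the alpha state).
- **Simulated tempering + constant-velocity pulling** — temperature ladders
  (300–400 K in 5 K steps; 300–380 K in 10 K steps), Metropolis rung
  exchange, Park–Pande initial weights, Wang–Landau adaptation, and pulling
  with exact per-increment work accounting on analytic model potentials.
- **Model systems** — analytic 1-D potentials with an exact (grid
  inverse-CDF) Boltzmann sampler and an overdamped Langevin integrator,
  Crooks-consistent Gaussian work pairs at known ΔG, and pseudo-N-SH2
  two-state structural ensembles with ground-truth labels, built so that
  every estimator in the package can be validated against a known answer.

Internal units are nm / kJ/mol / K / ps with k_B = 0.0083145 kJ/mol/K;
Ångström appears only at I/O boundaries (PDB files, order-parameter reports).

## Worked example

```python
import numpy as np
import nsh2kit as nk
from nsh2kit.analysis import superpose

res = nk.build_two_state_ensemble(n_frames=2000, alpha_fraction=0.7,
                                  noise_sd=0.3, seed=7)
ens, _ = superpose(res.ensemble, res.alpha_reference, nk.core_fit_selection())
cv = nk.pca(ens, nk.analysis_selection())[0]
ops = nk.order_parameters(res.ensemble)
cls = nk.classify_states(ops)
print(cv.variance_fraction, nk.pearson(ops.sheet, ops.pY), cls.alpha_fraction)
```

Running `python examples/two_state_analysis.py` (the same computation with
labels) prints:

```
core-fit RMSD (mean):      0.67 A
PC1 variance fraction:     0.44
R(sheet, pY loop):         -0.90
R(pY loop, +5 site):       +0.89
alpha fraction:            0.688  (95% CI 0.667-0.708)
true alpha fraction:       0.697
label accuracy:            0.990
```

The first PCA vector carries 44% of the fluctuations and the order
parameters co-vary with the allosteric signature (sheet spread
anticorrelated with pY-loop opening, pY-loop opening positively correlated
with +5-site opening). The quadrant classifier recovers the generator's
true 0.70 alpha fraction within its confidence interval and labels 99% of
frames correctly at 0.3 Å coordinate noise.

Each script in `examples/` demonstrates one capability end to end
(state analysis, WHAM, Crooks/BAR, simulated tempering, tempered pulling,
clustering/window seeding, and the crystal-structure sheet-distance check;
`examples/crystal_sheet_distance.py` accepts a PDB path such as a local copy
of the autoinhibited SHP2 structure 2SHP). A thin configuration-driven CLI
(`nsh2kit generate|states|cluster|wham|cft|temper --config cfg.yaml`) wraps
the same library calls for scripted, reproducible runs; every random
operation takes an explicit seed and identical configs produce
byte-identical outputs.

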