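# Methods

This note records the models, numerical choices, and validation logic of
`nsh2kit`, in the order the pipeline runs.

## Scope and validation strategy

The package implements the analysis machinery of a two-state (alpha/beta)
allosteric model of an SH2 domain: conformational-state analysis by PCA and
order parameters, GROMOS clustering and umbrella-window seeding, WHAM
free-energy profiles with Bayesian-bootstrap errors, Crooks/BAR
nonequilibrium free energies with thermodynamic cycles, and simulated
tempering coupled to constant-velocity pulling. All-atom molecular dynamics
is deliberately out of scope; every method is exercised on synthetic systems
whose ground truth is known exactly (analytic potentials, quadrature,
generator-stored labels, exhaustive re-implementations). Passing tests
therefore demonstrate that the estimators are correct and correctly coupled,
not that any particular protein system behaves a given way.

## Units and conventions

Lengths in nm, energies in kJ/mol, temperatures in K, times in ps;
k_B = 0.0083145 kJ/mol/K. Ångström appears only at I/O boundaries (PDB
files, RMSD and order-parameter reports) with explicit conversion. Work
sign convention: forward work is work done *on* the system for the 0→1
switch, reverse for 1→0; every work table states this in its header.
Free-energy profiles are reported with the minimum shifted to zero
("min-zero"), recorded in the output.

## Synthetic model systems

**1-D potentials.** Harmonic U = K/2 (x − x₀)² and symmetric double well
U = h[(x/a)² − 1]² (minima at ±a, barrier h at x = 0). Umbrella and pull
biases are harmonic, U_b = k/2 (x − ref)².

**Exact Boltzmann sampler.** Umbrella-window samples are drawn by inverse-CDF
sampling on a fine uniform grid (default 20 001 points) covering the region
where the total potential lies within 45 k_BT of its minimum, with a
trapezoidal CDF and linear interpolation. This is an exact i.i.d. sampler,
not a Markov chain, so WHAM validation is free of equilibration and
autocorrelation confounders. Discretization error at this grid density is
far below every test tolerance.

**Overdamped Langevin integrator.** Euler–Maruyama,
x ← x − (dt/γ) U′(x) + √(2 k_BT dt/γ) ξ. The deterministic map is a
contraction only if dt·max|U″|/γ ≤ 0.5 over the thermally accessible domain;
parameters violating this bound raise an error rather than diverging
silently, and a runtime excursion far outside the accessible domain aborts
with the step index. The first-order scheme inflates stationary variances by
≈ dt·k/(2γ); runs that feed quantitative work estimates use
dt·k/γ ≤ 0.05 so this bias stays below the statistical resolution of the
tests.

**Crooks-consistent work pairs.** Forward work ~ N(ΔG + βσ²/2, σ²) and
reverse work ~ N(−ΔG + βσ²/2, σ²) satisfy P_F(W)/P_R(−W) = exp[β(W − ΔG)]
identically, so the stored ΔG is the exact target for any estimator
consistent with the Crooks theorem. The default set size of 200 per
direction matches the fast-switching protocol the estimators are meant for.

**Two-state structural ensembles.** A pseudo-backbone of 101 residues
(numbered 3–103, atoms N/CA/C) lies on a smooth helix; six anchor atoms
(Lys35 CA, Thr42 CA, Gly39 C, Asn58 N, Tyr66 CA, Leu88 CA) are placed
symmetrically about their base-curve midpoints so that the three order
parameters hit the state targets exactly: alpha (9, 12, 7) Å and beta
(11, 4, 12) Å for (pY, sheet, +5). The beta state additionally displaces
loop atoms (residues 34–41 and 57–97, amplitude 0.18 nm; core residues
0.004 nm) along a smooth radial field, so the alpha→beta difference is one
distributed collective mode — with the default 0.3 Å isotropic coordinate
noise it carries ≈ 44% of the total variance, a realistic dominant-mode
fraction for a two-state domain. Frames are Bernoulli draws between the two
states; labels and the true mode are returned for recovery tests. The
default coupling signs (sheet vs pY negative, pY vs +5 positive) encode the
allosteric signature; flipping a sign reflects the corresponding beta target
about the alpha value and leaves the documented two-state geometry.
What the generator does **not** emulate: continuous transition paths
(frames sit at the two endpoints plus noise), anharmonic loop dynamics,
side chains, and solvent — so classification accuracies measured here are
upper bounds for real trajectories with intermediate conformations.
State populations are free parameters of the generator, not literature
values; the default 0.7/0.3 split simply exercises both states
asymmetrically. If the noise is large enough that the state distributions
overlap (4√2·noise_sd exceeding the smallest 2 Å state gap), the generator
records a warning in its log.

## Conformational-state analysis

**Superposition.** Kabsch (SVD with reflection guard) on a fit selection,
transform applied to all atoms; RMSD reported on the fit selection in Å.
Selections with fewer than 3 atoms or collinear geometry are rejected. The
canonical fit selection is the rigid core (residues 7–33, 40–47, 50–58,
61–65, 71–81, 88–90, 95–101); superposition is idempotent to < 1e−9 nm.

**PCA.** SVD of the centered frames × 3N coordinate matrix over the
analysis selection (backbone of residues 6–101; backbone = {N, CA, C, O}
when O atoms are present, {N, CA, C} otherwise). Eigenvalue λ_k = s_k²/(F−1);
variance fraction λ_k / trace. `pca` can superpose internally on a fit
selection (onto a supplied reference, defaulting to the first frame); the
projection-variance identity var(η) = λ₁ holds for the superposed frames.
Eigenvector sign is arbitrary, so vectors are oriented such that increasing
η increases the sheet-spread distance (toward the alpha state); when the
sheet anchors are outside the selection, the largest-magnitude component is
made positive instead.

**Subvectors.** Built by the two-step recipe: reconstruct the rank-1
trajectory mean + η₁·v, then run PCA restricted to the subset atoms. In
closed form the result equals the restriction of v to the subset,
renormalized; the implementation asserts |dot| ≥ 0.999 between the two
routes on every call and rejects subsets whose restriction norm is < 1e−8.

**Classification.** Quadrant rule on the pY-loop and +5-site distances:
alpha iff both below threshold (closed/closed), beta iff both above,
otherwise mixed. Default thresholds are the midpoints of the state
reference values — pY 10 Å, sheet 8 Å, +5 9.5 Å — because the model states
are given as centroids, not boundaries; thresholds are overridable and
recorded on the result, and thresholds outside the data range are logged.
Fractions carry 95% Wilson intervals. An alternative mode classifies in the
plane of the two subvector projections with thresholds at the midpoint of
the projected reference geometries. The sheet distance is deliberately not
part of the quadrant rule (it is the reaction coordinate of the profile
calculations); the three pairwise Pearson correlations are all exposed and
interpretation is left to the caller.

## GROMOS clustering and window seeding

Pairwise RMSD after per-pair Kabsch fitting (symmetric by construction; the
triangle inequality can be violated only within superposition tolerance
because each pair is fitted independently). Greedy clustering: the frame
with the most neighbors within the cutoff becomes a center, its cluster is
removed, repeat; ties break toward the lowest frame index so results are
deterministic and invariant under relabeling up to that rule. The cutoff is
the abscissa of the first local maximum of the off-diagonal RMSD histogram
(Freedman–Diaconis bins, 3-bin moving-average smoothing — "first relative
maximum" is ill-defined on raw noisy histograms); a distribution with no
interior maximum falls back to the median with a logged warning. The
histogram uses all off-diagonal pairs. Window seeding partitions a pulling
trace into uniform reaction-coordinate intervals and returns, per interval,
the center of the largest cluster; intervals with fewer than 10 frame pairs
fall back to the median pair distance as cutoff, and one- or two-frame
intervals take their first frame.

## WHAM

Self-consistent iteration of the standard equations on histograms over
(default) 200 uniform bins spanning the sampled range, bias evaluated at
bin centers, until max|ΔF_i| < 1e−4 kJ/mol (max 1e5 iterations; both
configurable — no convergence criteria are canonical for this method).
Non-convergence raises with the last residual; adjacent windows (by
reference) whose sampled ranges do not touch raise an error naming the gap,
and pairs sharing no occupied bin are logged as warnings. Empty bins are
dropped from the profile rather than reported as infinite. Single-temperature
WHAM only. On a single unbiased window the solution reduces to
−k_BT log(histogram) up to offset, which is tested.

Recovery accuracy is quoted over the span of the window references: bins in
the exponential tails beyond the outermost windows hold a handful of samples
and their ~k_BT/√n statistical noise says nothing about the estimator. With
24 exact-sampled windows (k = 1000 kJ/mol/nm², 2·10⁴ samples each) across a
K = 50 kJ/mol/nm² harmonic landscape the profile matches ½Kx² within
≈ 0.15 kJ/mol over the window span.

**Bayesian bootstrap of complete histograms.** Each replicate draws one
i.i.d. exponential weight per *window* (normalized — the Dirichlet/Bayesian
bootstrap), re-solves WHAM with the weighted histograms, and aligns the
replicate to the unweighted profile by the mean over shared bins; the
per-bin error is the standard deviation over replicates (default 100 — a
config default, since no canonical replicate count exists). Weights attach
to whole windows, never individual samples: the window histogram is the
independent unit of the calculation. Identical windows therefore give zero
error, and errors shrink as per-window sample counts grow.

## Crooks/BAR estimation and cycles

**BAR** solves Σ_F f(β(W_i − ΔG + M)) = Σ_R f(β(W_j + ΔG − M)) with f the
logistic function and M = k_BT ln(n_F/n_R), by Brent root-finding on the
bracket [min(−W_R), max(W_F)] expanded by 10 k_BT (tolerance 1e−6 kJ/mol);
the residual is monotone in ΔG so the root is unique. Forward and
reversed-reverse distributions separated by more than 50 k_BT raise an
error advising more sampling. BAR is the primary estimator because it is
the maximum-likelihood solution under the Crooks relation; the
**crossing-point** estimate (Gaussian KDE with Silverman bandwidth for both
P_F(W) and P_R(−W), intersection within the overlap region, nearest to the
pooled mean if noise creates several) is kept as a diagnostic and
cross-check, since the two should agree within combined errors on
Crooks-consistent data. Errors come from bootstrap resampling of both
directions independently (≥ 50 replicates; an estimator failing on > 20% of
replicates aborts). Tests cross-check BAR against an independent route that
minimizes the BAR negative log-likelihood directly.

**Cycles.** ΔΔG = ΔG_bound − ΔG_unbound with errors in quadrature, legs
required to share a temperature. For the alpha-vs-beta-preference context
the sign convention is fixed: positive ΔΔG = augmented preference for the
alpha (activating) state. Closed four-state cycles (mutate-then-bind vs
bind-then-mutate) compose to identical ΔΔG by construction.

## Simulated tempering and pulling

Rung exchange is nearest-neighbor Metropolis with acceptance
min{1, exp[−(β_j − β_i)U + (f_j − f_i)]}, giving stationary rung occupancy
∝ Z_i e^{f_i}; the exact flattening weights are f_i = β_i F_i. Initial
weights come from the Park–Pande trapezoid f_{i+1} = f_i +
(β_{i+1} − β_i)(Ē_i + Ē_{i+1})/2 over per-rung mean energies. Wang–Landau
adaptation decreases the visited rung's weight by δ (suppressing
over-visited rungs) and, when the visit histogram is flat (min/mean ≥ 0.8),
halves δ and resets the histogram; defaults δ₀ = 1, scale 0.5. The flatness
test is only evaluated once the histogram holds ≥ 100 mean visits per rung —
testing a near-empty histogram would shrink δ before the weights
equilibrate, freezing in early-stage error. On the 21-rung 300–400 K ladder
with a harmonic oscillator, weights run to δ < 1e−4 reproduce the exact
β_iF_i profile within ≈ 0.1 (best additive constant removed); occupancy with
exact weights is uniform within multinomial error once the ladder diffusion
time (~2 × n_rungs attempts) is accounted for in the variance. Ladder
presets: 300–400 K in 5 K steps and 300–380 K in 10 K steps, constructible
by name. Tempering runs are tagged constant-volume in their run records.

**Pulling.** The harmonic pull reference advances at constant velocity;
work is accumulated per reference increment at fixed configuration,
W += k(ref_new − ref_old)(ref_mid − ξ), which is the exact ΔU of the bias
change (the midpoint form is algebraically exact for a harmonic bias, and
gives W ≡ 0 at v = 0 and the reversible limit as v → 0). Multiple replicas
integrate vectorized, each at its own rung temperature; frames at the base
rung are flagged for downstream window seeding. Collective-variable
restraints are harmonic in the projection η with gradient purely along the
collective direction; orthogonal degrees of freedom are untouched.
Forward/reverse pull ensembles start from exact Boltzmann draws of the
restrained end states, so their work distributions target the quadrature
free-energy difference between those states — the oracle used by the tests.

## Problem sizes

The validation suite uses 10⁵-sample exact draws for sampler checks, 24
windows × 2·10⁴ samples for WHAM, 50 independent 200+200 work sets for BAR
coverage, 10⁵ tempering attempts for occupancy, ≤ 2·10⁶ capped attempts for
Wang–Landau convergence, 2000-frame ensembles for state recovery, and
200 + 200 pulls for the work-estimator checks — sizes at which every
tolerance above is resolved with comfortable statistical margin.

## Known limitations

- The artifact validates estimators on toy ground truth; it makes no claim
  about force-field MD observables (profiles, mutation ΔΔG magnitudes,
  correlation coefficients of real trajectories).
- The crystal-structure distance check runs on any user-supplied PDB file,
  but the repository ships only a synthetic autoinhibited-domain model
  (labelled synthetic) for exercising that code path.
- PDB reading rejects insertion codes rather than renumbering; altloc keeps
  the first location.
- The Langevin integrator is first-order (Euler–Maruyama); its O(dt)
  stationary bias is documented above and bounded in tests, not eliminated.
- WHAM is single-temperature; no MBAR-style multi-temperature combination.
- GROMOS clustering is O(n²) in frames and is meant for the window-seeding
  scale (tens to hundreds of frames per interval), not whole trajectories.
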