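# Methods

This note records the models implemented in `allokin`, the choices made where
the field's conventions leave room, and what the synthetic-data tests do and
do not establish about real measurements.

## Chemical-shift perturbations

Combined amide CSPs use Δδ = √((ΔδH)² + (w·ΔδN)²) with the standard ¹⁵N
weight w = 0.154 that puts both nuclei on a comparable ppm dispersion; the
weight is an argument everywhere it enters (CSP, trajectory projection,
CONCISE).  Responder flagging uses the conventional profile threshold
mean(Δδ) + k·SD(Δδ) with k = 1 by default.  SD *about the mean* (not about
zero) was chosen because the profile's mean is dominated by non-binding
residues and acts as the per-dataset noise floor; `sd_multiplier` exposes k.

## CHESCA

**Inclusion filter.** A residue enters the covariance analysis only if, for
at least one pair of states (A, B) and at least one dimension, its shift
change exceeds the mean of its two linewidths, |δ(A) − δ(B)| > (Δν_A + Δν_B)/2.
Which pair satisfies the inequality is irrelevant.  Linewidths are treated
per-dimension and symmetric (one Δν per nucleus per state).  Tables without
linewidths fall back to 0.03 ppm (¹H) / 0.3 ppm (¹⁵N) with a loud warning —
values typical of a well-behaved 40 kDa TROSY spectrum — or raise if the
fallback is disabled.

**Trace projection.** Correlations are computed between 1-D traces: each
residue's per-state (δH, w·δN) points are mean-centered and projected on
their first right singular vector.  The singular-value ratio s₁/s₂ measures
trajectory linearity (∞ when collinear to machine precision; s₂ below
1e−9·s₁ is treated as zero).  Projecting before correlating makes |Pearson|
well-defined per residue pair when the two nuclei disagree; correlating a
single nucleus instead is available via `method="proton"|"nitrogen"`.

**Matrix and scores.** R_ij = |Pearson| between traces (absolute value: an
anti-correlated linear response is still a coordinated response).  The
network cutoff is 0.98; correlation scores count partners with R_ij > cutoff
and divide by a fixed denominator — the number of analyzed residues by
default, settable to a constant such as 350 (the residue count of the intact
kinase) when profiles from differently filtered datasets must share a scale.
Zero-variance traces (static residues) have no defined Pearson coefficient
and are dropped with a warning rather than imputed.

**Clustering.** Agglomerative clustering (average or complete linkage,
`scipy.cluster.hierarchy`) on distance 1 − R_ij, cut at 1 − cutoff by
default; only clusters of ≥ 2 residues receive labels.

**Community matrix.** For communities X ≠ Y,
R_X,Y = #{(i ∈ X, j ∈ Y): R_ij > 0.8}/(n_X·n_Y) with n counted over scored
residues only.  The within-community diagonal divides the unordered distinct
pair count by n_X(n_X − 1)/2, since the n_X·n_Y form double-counts ordered
pairs and has no natural meaning for self-pairs.  A community reduced to
fewer than two scored residues yields an undefined (NaN) diagonal entry, not
zero — absence of evidence is not zero coupling.

## CONCISE

Per residue, the same 2-D PCA as above; residues with s₁/s₂ < 3 are excluded
as insufficiently linear (the admission threshold is configurable; 3 keeps
clearly linear trajectories while rejecting isotropic noise at the 4-state
design).  Admitted score traces are standardized per residue (z-score), so
every residue contributes equal weight regardless of its response amplitude.
Per-residue axis signs, arbitrary from the SVD, are aligned in two passes
(first to one reference trace, then to the consensus mean trace), and the
global axis is flipped if needed so the apo state has the minimum ⟨PC⟩.
Each state's pooled scores are summarized by a maximum-likelihood Gaussian
(mean = sample mean, SD = population SD): ⟨PC⟩ is the mean; the SD measures
how coordinated the residue responses are, and broadens when fewer residues
share the latent coordinate.

Standardizing before pooling is a genuine design choice (alternatives exist
that weight residues by amplitude); it makes ⟨PC⟩ of a perfectly coordinated
dataset equal the standardized latent coordinate itself, which is the
behavior the recovery tests pin down.

**Free-energy mapping.** % closed interpolates ⟨PC⟩ linearly between an open
and a closed reference state (values outside [0, 100] are reported and
flagged, not clipped).  ΔΔG is affine in % closed with anchors
(0 %, 0 kcal/mol) and (100 %, ΔΔG_ref); the default ΔΔG_ref = −15 kcal/mol
in kcal/mol units is consistent with summing RT·ln Kd at 300 K over the
wild-type's sequential nucleotide (83 μM) and pseudo-substrate (0.16 μM)
binding steps (−5.60 − 9.33 ≈ −14.9 kcal/mol).  Per-state uncertainty is the
Gaussian SD scaled by |ΔΔG span|/|⟨PC⟩ span|.

## ITC thermodynamics

The 1:1 isotherm derivative is derived from the binding mass balance
Θ² − Θ(1 + Rm + r) + Rm = 0 (Θ bound fraction, Rm molar ratio,
r = Kd/[M]tot):

    dΘ/dRm = 1/2 + (1 − (1+r)/2 − Rm/2) / √(Rm² − 2Rm(1−r) + (1+r)²),

scaled by ΔH°·V₀.  This form satisfies all three limits — value ΔH°·V₀ at
the start of a tight titration, → 0 at saturation, and → 0 for very weak
binding — and is cross-checked in the tests against a numerical derivative
of the binding polynomial.  Fitting uses `scipy.optimize.least_squares` on
(log Kd, ΔH°) with the stoichiometry fixed at 1 (free n behind a flag); the
log-parameterization keeps Kd positive and the initial Kd comes from a
deterministic log-spaced scan, so fits are reproducible.  All-zero heats are
reported as ΔH° = 0 with Kd = NaN and a warning rather than a spurious fit.

ΔG = RT·ln Kd with R = 1.9872×10⁻³ kcal/(mol·K), Kd converted from μM to
molar; TΔS = ΔH − ΔG exactly.  σ = Kd(apo)/Kd(nucleotide-bound); fold labels
round half away from zero, which reproduces every integer fold implied by
the printed constants (2, 4, 7, 13).

## Kinetics

Unweighted least squares on v = Vmax·S/(KM + S) (no weighting scheme is
standard for 6–8-point initial-velocity grids); standard errors from the fit
covariance.  kcat = Vmax/[E] requires the enzyme concentration as explicit
user input.  kcat/KM uses quadrature propagation,
σ_rel(eff) = √(σ_rel(kcat)² + σ_rel(KM)²), treating [E] as exact.

## Synthetic data

The generator emulates fast-exchange two-state averaging: state s sits at a
latent closure coordinate λ_s ∈ [0, 1] and each networked residue moves as
δ_i(s) = δ_i⁰ + a_i·λ_s + ε with ε ~ N(0, noise_sd).  Defaults: 100
residues, 60 % networked, λ = (0, 0.45, 0.55, 1.0) for apo/ADP/ATPγN/ternary
(binary complexes midway on the equilibrium), ¹H responses of order 0.15 ppm
and ¹⁵N of order 1 ppm, noise 0.005/0.05 ppm, linewidths 0.02/0.2 ppm.
Off-network residues receive independent per-state displacements drawn from
the same noise model, so they exercise the inclusion filter without carrying
a shared signal.  A single seed spawns one deterministic sub-stream per
residue; outputs are byte-stable.  Optional per-community λ overrides model
communities that stop short of the fully closed state.

What this emulates — and what it does not: real spectra add exchange
broadening, peak overlap, assignment gaps correlated with dynamics, and
non-linear (multi-state) trajectories.  Passing the recovery tests therefore
shows the estimators are correct under the stated statistical model, not
that the model captures every pathology of experimental data.

Simulation-study sizes used by the test suite: 20 seeds × 100 residues for
equilibrium-rank recovery, 3 seeds × 200 residues × 3 network fractions for
the density-broadening comparison, 20 seeds for noisy isotherm/velocity
refits — sizes at which the checked contrasts are stable across reruns.

## Degenerate inputs and tie-breaks

- Residues missing any analyzed state are excluded (and logged), matching
  the reality that 10–15 % of amides are typically unassigned.
- Pearson against a zero-variance trace: residue dropped, never NaN in the
  matrix.
- SVD sign ties (zero dot product with the consensus) resolve to +1.
- `percent_closed` with coincident references raises rather than dividing by
  zero.

## Known limitations

- CHESCA correlations at 4 states have only 2 degrees of freedom; with noisy
  data, high |Pearson| values arise by chance and the 0.98 cutoff is
  meaningful only jointly with the linewidth filter, as in the original
  protocol.
- The ITC module fits pre-integrated, dilution-corrected heats; raw
  thermogram processing is out of scope.
- Enzyme concentrations for kcat are user inputs; no attempt is made to
  infer them.
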