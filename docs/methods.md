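# Methods

This note records the models implemented in `neqbind`, the conventions
and defaults that matter, what the synthetic generators do and do not
emulate, and the numerical choices behind the estimators.  Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Units and constants

Internal energy unit is kJ/mol (the GROMACS convention), with
k_B = 0.0083144621 kJ/(mol·K).  Reported tables use kcal/mol via the
exact conversion 1 kcal = 4.184 kJ (4184 J for entropy terms).  Entropy
computations convert to SI internally (amu → kg, nm → m,
ħ = 1.054571817·10⁻³⁴ J·s) and report per mole through Avogadro's
number.  Default temperature is 300.15 K (a 298 K variant is used by
some protocols and is a plain parameter everywhere).

## Work and free-energy estimation

A transition's work is the trapezoidal integral of ∂H/∂λ along the
series' own λ path.  **Sign convention:** reverse works are stored as
measured along the 1→0 transition — the raw output of an MD engine —
and never pre-negated.  Estimators negate internally where the theory
needs work expressed along 0→1.  Files with NaN/inf values are rejected
with the offending file named; nothing is dropped silently.

The **maximum-likelihood (BAR) estimator** solves the Bennett
self-consistency equation including the sample-count offset
M = β⁻¹ln(n_f/n_r).  The root is bracketed by the pooled range of
forward and negated-reverse works, expanded geometrically (up to ~10×)
if needed, and solved by Brent's method to a residual below 10⁻¹⁰.
Because the residual is strictly monotone in ΔG a root formally always
exists; *non-overlap* is therefore diagnosed from the mean Fermi
overlap ⟨f(1−f)⟩ at the solution (below 10⁻¹⁰ → error with diagnostic,
no silent extrapolation), which is also the quantity whose inverse
enters the analytic asymptotic variance (the default uncertainty;
bootstrap is available and agrees within a factor ~2 on Gaussian sets).

Companion estimators: **Jarzynski** (log-sum-exp exponential averaging;
its estimate never exceeds the mean work, and its bootstrap error is
known to be optimistic for dissipative distributions) and the **Crooks
Gaussian intersection** (quadratic solve for the crossing of the two
fitted normals, root taken between the means; the equal-variance
degenerate case is the midpoint analytically).  On work sets that
satisfy the Crooks theorem with Gaussian distributions all three agree
with the generating ΔG within statistical error; this is asserted in
the tests.

## Binding assembly

**Restraint correction.** The standard-state release free energy of the
six-coordinate harmonic restraint set (distance r₀; angles θ_A, θ_B;
three dihedrals) uses V° = 1.6605 nm³ and the closed form quoted in the
README.  Two analytic evaluations are provided:

* `jacobian="reference"` (default): the volume element r² sinθ_A sinθ_B
  evaluated at the reference geometry — the textbook stiff-spring form.
* `jacobian="exact"`: the exact Gaussian moments ⟨r²⟩ = r₀² + kT/k_r and
  ⟨sinθ⟩ = sinθ₀·e^{−kT/(2k_θ)}, which reproduce the full 6-D
  configurational integral to numerical precision whenever the Gaussian
  mass lies inside the physical domain.

The distinction matters at production-like constants: with angular
springs of ~42 kJ/(mol·rad²) at 300 K the reference-Jacobian form sits
≈0.14 kJ/mol from the true integral, while the exact form agrees to
<10⁻⁵ kJ/mol (both facts are asserted against quadrature in the tests).
The default remains the reference form because it is the correction
conventionally applied in production workflows.

**Sign assembly.** In the double-system/single-box setup one box holds
the guest bound (and a second copy decoupled in solvent); which end of
the alchemical path is "bound" is a declared convention, not an
inference.  `dssb-unbinding` (default) means the A→B transition is
unbinding, so ΔG_bind = −ΔG_transition + ΔG_restr; the opposite
convention flips only the transition term.  The parameter is logged in
every provenance record.

**Pose combination.** The two guest orientations are mutually exclusive
states, so the default combination is the Boltzmann sum
ΔG = −kT ln Σ e^{−βΔGᵢ} over non-discarded poses (log-sum-exp
evaluated); the result always lies in [min ΔGᵢ − kT ln n, min ΔGᵢ].  A
Boltzmann-weighted mean is available behind a flag for comparison with
workflows that use it.  Uncertainties propagate to first order with the
Boltzmann weights.  Poses flagged by the event filter (flip/unbind) are
carried as explicit discarded records; combining an all-discarded set
is an error surfaced with the reasons, matching the practice of
dropping poses too weakly binding to contribute.

**Averaging.** Repeats: arithmetic mean with SEM = s/√n; a single
repeat yields a flagged undefined SEM rather than zero.  Force-field
consensus: mean with quadrature error (1/n)√(Σσᵢ²); for the canonical
two-field worked example (−6.76 ± 0.38 and −5.25 ± 0.11 kcal/mol) this
gives −6.005 ± 0.198 kcal/mol, recomputed by the acceptance script.

**Metrics.** AUE and Pearson r with uncertainties from paired bootstrap
over systems (seeded, deterministic).  Bootstrapping over systems, not
repeats, is the default because the per-system errors are already SEMs.
Zero-variance inputs flag r as undefined instead of raising.

## Conformational analysis

**Superposition** is a per-frame Kabsch fit (proper rotation enforced)
over the analysis selection; the common reference is the mean structure
of the pooled ensembles, iterated twice — a standard, testable choice.
Collinear selections are rejected.

**Schlitter entropy** is evaluated through the eigenvalues of the
symmetrized mass-weighted covariance in SI units, via log1p, so the
+1 identity term regularizes rank-deficient covariances exactly as in
the formula.  The ensemble must be superposed first (or the caller must
assert alignment for ensembles aligned by construction); hydrogens are
excluded through the *selection* only — masses of selected atoms are
used as-is.  The estimator is an upper bound and is invariant (<0.5%)
under per-frame rigid motion once frames are re-fitted; both properties
are tested.

**Entropy contribution to binding** is T·(S_holo − S_apo) in kcal/mol:
negative when the unbound state is entropically richer.  This
interpretation reproduces every published holo/apo → contribution row
used in the acceptance checks within the rounding of the printed
inputs.

**PCA / free-energy surfaces.**  PCA is non-mass-weighted, on heavy-atom
Cartesian coordinates of the pooled (apo + holo) superposed ensembles;
eigenpairs are sorted by descending eigenvalue and the sign fixed by
making each eigenvector's largest component positive.  Mass weighting
is deliberately not applied (the conventional choice for visualizing
host conformational space); the covariance trace equals the summed
eigenvalues to 10⁻¹⁰ relative.  The FES over PC1/PC2 is
−kT ln(n/n_max) per bin, so the modal bin is exactly 0; empty bins are
masked, never set to zero.  Frames labelled unbound by the event filter
can be excluded before histogramming (surface-binding states filtered
out).

**Event filtering.**  Frame labels (primary/secondary/unbound) follow
the sign of the orientation cosine with hysteresis: a state change
commits only after |cos| exceeds the band on the new side for a
persistence window, and unbinding requires the COM distance to exceed a
cutoff for the same window.  Defaults: band 0.2, cutoff 1.5 nm,
persistence 50 frames — the filtering thresholds are not standardized
anywhere, so they are config-exposed and the defaults are chosen to
reject single-frame noise at cosine noise levels ≲0.15 while dating a
true flip to within ±20 frames (verified over seeded sweeps).  The
verdict (clean / flipped(frame) / unbound(frame)) reports the first
committed departure; an all-noise series yields a low-confidence flag.

## Force-field linting

A dihedral parameter file is flagged for an atom-type quadruple
(canonicalized over reading direction) iff three conditions hold
simultaneously: no wildcard types; at least two disjoint parameter sets
sharing ≥1 multiplicity with differing barrier or phase; and the sets
are non-sequential (separated by unrelated lines).  "Sharing a
multiplicity" is the operative reading of *identical multiplicities*:
re-definitions with fully disjoint periodicities are legitimate
multi-term dihedrals and are not flagged, and a contiguous multi-term
block is one set by construction.  AMBER barriers are converted
kcal→kJ at parse time with the dialect recorded; negative periodicities
are continuation flags and retained.  Detection achieves recall 1.0
with zero false positives on 1000 generated fixtures (recomputed by the
acceptance script).

Topology policies: *first-match* (earliest set), *preferred-variant*
(predicate-selected; default = highest per-term force constant, the
sugar-specific choice), *all-variants* (every term of every set at
once, the over-defining interpretation).  All three are idempotent and
preserve assignment order; the inline k written to GROMACS function-9
lines is PK/IDIVF.  Charge scaling multiplies only the selected atoms'
charges and reports the net-charge change (factor−1)·Σq; the atom
selection is user-supplied (which atoms constitute a "sidechain" is
system-specific).

## Synthetic data: what it emulates, what it does not

* `gen_gaussian_work` draws forward works from N(ΔG + βσ²/2, σ²) and
  measured reverse works from N(−ΔG + βσ²/2, σ²) — the unique Gaussian
  pair with symmetric dissipation satisfying the Crooks theorem
  exactly, verified by a histogram log-ratio regression (slope β, root
  ΔG).  Default study conditions mirror a bidirectional protocol:
  3 repeats per pose, tens of transitions per direction per repeat
  (production protocols use 151; tests and the acceptance script use
  15–30 per repeat, and n = 500/500 for estimator validation, to keep
  desk-scale runtimes), σ = 2 kJ/mol work spread, T = 300.15 K.
* `gen_gaussian_ensemble` samples i.i.d. multivariate normal frames
  with a prescribed 3N covariance — the regime where Schlitter's
  formula is exact — plus an optional mean structure for superposition
  tests.
* `gen_pose_series` plants step-function flip/unbind events with
  Gaussian observation noise.
* `gen_ff_fixture` emits AMBER dihedral blocks with injected
  over-defined groups placed non-adjacently, returning the ground-truth
  list.
* `gen_dhdl_series` evaluates a polynomial ∂H/∂λ with its analytic
  integral as oracle.

Real data differ in ways the generators do not model: work
distributions are skewed and heavy-tailed at fast switching rates,
coordinate fluctuations are anharmonic and correlated in time (the
Schlitter value is then strictly an upper bound, not the entropy),
flips are gradual rather than instantaneous, and parameter files embed
dihedral blocks in full force-field context.  Passing tests therefore
demonstrate correctness of the estimators and transforms on their
stated models, not the sampling adequacy of any simulation.  Headline
challenge-style accuracy numbers (AUE/Pearson against experiment)
require the original MD ensembles and are out of scope; the metrics
stage is validated on synthetic references only.

## Numerical choices and edge cases

* Root bracketing for the ML estimator as above; residual tolerance
  10⁻¹⁰ kJ/mol; grid-oracle agreement asserted to 10⁻⁶ kJ/mol.
* CGI takes the intersection root between the two means; if sampling
  noise pushes both roots outside, the root nearest the midpoint is
  used.  Zero variance in either direction is an error.
* Bootstrap resampling is within-direction, seeded with
  `numpy.random.default_rng`; estimator failures on a resample name the
  resample index.
* Schlitter eigenvalues are clipped at zero before log1p (they can be
  −ε from round-off); covariances are symmetrized before `eigvalsh`.
* FES bins: the histogram range adapts to the projected data; masked +
  occupied bins always partition the grid.
* Degenerate inputs: empty manifests, missing files, mixed host/guest
  labels, duplicate hosts, collinear restraint geometries and
  non-finite works all raise with specific messages rather than
  propagating NaNs.

## Known limitations

Multi-state MBAR, λ-schedule optimization and equilibrium TI are out of
scope, as are water/ion modelling, atom-type assignment (the linter
audits parameter files and topologies, not typing engines), SASA and
interaction-energy analyses, and binary trajectory formats (text
XYZ/CSV dialects are supported; binary readers from mdtraj/MDAnalysis
can be used upstream to produce them).  Improper dihedrals are excluded
from over-definition detection.  The Jarzynski stderr underestimates
for strongly dissipative work sets by construction.
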