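# Methods

This note records the models, conventions, and parameter choices behind
`loadpath`, and what its synthetic fixtures do and do not emulate.

## The fixture landscape

The loading landscape is an analytic 2D surface over the ligand's
collective-variable (CV) plane:

    F(x, y) = A (ρ − R)² + (Δ/2)(1 − cos θ) + c₂ (1 − cos 2θ)
              + h [g(θ − π/2) + g(θ + π/2)],

with (ρ, θ) polar coordinates, g a wrapped Gaussian of angular width σ, and
defaults R = 2 Å, A = 5 kcal/mol/Å², Δ = 2.5 kcal/mol, σ = 0.35 rad,
c₂ = Δ/4. The radial term confines motion to a ring (the geometric stand-in
for the ligand's passage around the protein surface); the first harmonic
tilts the ring so the active site (θ = 0) sits Δ below the interface
(θ = π); the second harmonic gives θ = π positive curvature so the interface
is a true basin bottom (with the first harmonic alone, θ = π would be a
local maximum of the angular profile and the basin would bottom out at the
bump feet — any c₂ > Δ/8 fixes this; Δ/4 is used). The two Gaussian bumps
create the branch saddles. Their common height h is calibrated by bisection
on the 1D angular profile so the branch maximum sits exactly H = 4.2 kcal/mol
above the global minimum, and a final constant shift puts the active-site
minimum at exactly 0. Both basins receive identical bump leakage
(< 10⁻³ kcal/mol at σ = 0.35), so the interface−active offset is exactly Δ.

The surface is mirror symmetric about the axis through the minima, so the
two branches carry *exactly* equal barriers; a real system's two pathways
are only nearly equivalent. An optional `bump_asymmetry` parameter breaks
the tie. Energies are labelled kcal/mol and lengths Å throughout; the
landscape is unitless in substance and the labels only keep the printed
constants usable without conversion gymnastics.

Nothing here models actual protein geometry, ligand chemistry, or
force-field energetics: the fixture is built to *carry* the printed
landscape features (0 / 2.5 / 4.2 / 1.7 kcal/mol), so pipeline tests
demonstrate that the estimators recover known truth, not that the truth is
biologically derived.

## Toy dynamics

Sampling uses the Euler–Maruyama discretization of overdamped Langevin
dynamics in CV space,

    x ← x − ∇(F + V_bias) dt/γ + √(2 kT dt/γ) ξ,

with stationary distribution ∝ exp(−F/kT). There is no inertia — CV-space
toys need none, and correctness proofs (harmonic variance kT/k, χ² and KS
histogram checks against exp(−F/kT)) are simplest in the overdamped limit.
`run_langevin` defaults are dt = 10⁻³, γ = 1, kT = k_B·300 K =
0.596 kcal/mol; stride-thinning is part of the sampler so sample counts are
reproducible from the configuration alone. A divergence guard raises when
any coordinate leaves a configured domain bound.

The exit restraint is the one-sided moving wall
V_bias = k_bias min(r − r₀(t), 0)², r₀(t) = r(0) + c·t, flat for
r ≥ r₀(t) and continuous in value and force at the wall. The printed bias
constant "10 kJ Å⁻²" lacks a per-mol; it is interpreted as 10 kJ/mol/Å²
(= 2.390 kcal/mol/Å²) for dimensional consistency with every other constant,
and the original string is preserved in the config field name
(`k_bias_kj_mol_a2`). Unit conversions use 1 kcal = 4.184 kJ and
1 nm = 10 Å exactly, reproducing 2.39 and 0.48 kcal/mol/Å² from 1000 and
200 kJ/mol/nm².

## Guiding path, string method, replica exchange

The guiding path is a closed loop of 48 points; indices 0 (interface) and
24 (active site) are pinned, and windows 47 and 0 are ring neighbours.
Umbrella restraints use the convention **V_w(x) = k |x − center|²** (no ½),
with k in kcal/mol/Å² — 2.39 during the string phase, 0.48 in production.
The convention is stated in every output header; with both unit systems
printed but no formula given for the restraint, any fixed convention is
acceptable provided it is declared, and round-trip unit conversion is tested
regardless.

String optimization repeats: sample every window with Langevin dynamics
(first 25% discarded as equilibration), move each unpinned point to its
window's sample mean, smooth with p_i ← (1−2κ)p_i + κ(p_{i−1}+p_{i+1})
(cyclically, κ = 0.1), and reparameterize to equal arc length per pinned
segment (iterated until consecutive chords agree to ~10⁻¹² relative, so
reparameterization is idempotent and exactly preserves the pins). The
update stops early when the maximum point displacement drops below a
tolerance; because the sample means are stochastic, the practical tolerance
is set by the mean's Monte-Carlo error, and a budget exhaustion is reported
as a warning plus a `converged=False` flag, never silently. The drift
estimator (window means), smoothing constant, and tolerance are this
package's defaults; the upstream protocol names the method but not these
knobs.

Replica exchange attempts neighbour swaps in alternating even/odd edge
phases around the full ring (including edge 47–0) every 100 integrator
steps, accepting with the Metropolis probability
min(1, exp(−[V_i(x_j)+V_j(x_i)−V_i(x_i)−V_j(x_j)]/kT)). Exchange changes
mixing, not the per-window target distribution — verified by a KS test of
window marginals with and without exchange.

## Free-energy estimation

All windows share one unbiased surface, so the reduced potentials entering
MBAR are the biases alone, u_k(x) = V_k(x)/kT. The solver minimizes the
convex MBAR objective over gauge-fixed free energies (L-BFGS, f₀ = 0),
polishes with self-consistent iteration, and reports the final residual
(tolerance 10⁻⁸, error on failure). Unbiased weights
w_n ∝ 1/Σ_k N_k exp(f_k − u_k(x_n)) are normalized to 1. No
autocorrelation subsampling is applied by default: stride-thinning already
spaces samples, and determinism is preferred for tests.

The PMF is F(cell) = −kT ln Σ_{n∈cell} w_n on a 60×60 grid over the sample
bounding box plus 5% padding (the upstream grid is unstated; resolution is
config-exposed and recorded), gauge-shifted so the occupied minimum is 0.
Unoccupied cells are flagged (NaN), never silently interpolated. Basin
values are read as the minimum over a 3×3 cell neighbourhood to suppress
single-cell binning noise; whether the original 2.5/4.2 values were read at
guiding points or grid minima is unstated, so this package uses grid minima
and says so. A binned WHAM solver over the same grid serves as an
independent oracle (agreement ≤ 0.1 kcal/mol RMS on shared occupied cells),
and a convergence diagnostic refits MBAR on the first 75% of each window's
samples and reports the RMS difference of the two PMFs — mirroring a
partial-versus-full-data convergence check.

## Paths and barriers

Minima are occupied cells with no strictly lower occupied 8-neighbour;
exact-tie plateaus (which arise on symmetric analytic grids) merge into one
candidate, flat surfaces yield none, and candidates must clear a topographic
prominence threshold (default 0.5 kcal/mol, config-exposed) and a minimum
cell occupancy (default 5 samples — basin bottoms are by construction among
the best-sampled cells, while stray outskirt cells carry large noise).

The MFEP is a zero-temperature string on the bilinearly interpolated grid:
endpoints pinned at the minima, points relaxed down the normal component of
the gradient with equal-arc reparameterization each step; branch-constrained
extraction ("upper"/"lower", the counterclockwise/clockwise half-planes of
the segment between the minima) initializes as a semicircular arc and clamps
to its half-plane. On sampled PMFs, paths and barriers are extracted on an
occupied-neighbourhood 3×3 box average of the grid: a path's running maximum
over noisy cells is biased upward by roughly one cell noise s.d., and the
averaging cuts that threefold while shifting the surface only by
~Laplacian·spacing²/3 (≲ 0.02 kcal/mol at default resolution). The barrier
convention follows the source protocol: peak = maximum along the path in the
global-minimum gauge, baseline = interfacial minimum, barrier = peak −
baseline.

The independent oracle is an exact widest-path (minimax) search over the
8-connected occupied grid — the minimum over connecting paths of the maximum
cell value, computed by a Dijkstra-style sweep with lexicographic
tie-breaking. It lower-bounds any continuous path's peak up to grid
resolution; string and minimax peaks agree within 0.15 kcal/mol on the
fixture. Transition-state resampling draws, per grid cell, n = 100
structures with replacement with probability proportional to the unbiased
weights; the "highest energy states along two paths" are taken as the single
argmax cell per branch, since the upstream text does not define the cell
set.

## The default study configuration

`StudyConfig()` reproduces the protocol shape: 48 windows, pins {0, 24},
k_string = 2.39 and k_production = 0.48 kcal/mol/Å², 20 time-units of
production per window (48 × 20 = 960 total, the accounting identity checked
in the report), exchange every 100 steps, kT at 300 K, 60×60 grid. The toy
dynamics run in a fast-diffusion regime (γ = 0.05, dt = 2.5×10⁻⁴, chosen
against the stability bound dt < 0.2 γ/k_max for the stiffest landscape
mode): with the position relaxation time γ/2k ≈ 0.05 time-units, each
window's nominal 20 time-units contain several hundred independent samples
and the reconstructed offset and barriers land well inside ±0.3 kcal/mol of
the construction values. The whole study is a pure function of
(config, seed): all generators are spawned from the config seed, and a rerun
reproduces the report bit for bit.

The exit study runs eight 90-time-unit trajectories from one coordinate with
distinct seeds under the moving wall (c = 0.1, so r₀ advances 9.0 length
units), over a deliberately shallow radial well (k = 0.05 kcal/mol/Å²) so
the wall, not the well, dominates the exit; the particle tracks the wall
within 3√(kT/k_bias). RMSF windows span 20 time-units, trailing partial
windows are dropped rather than padded, and tables average over the eight
runs.

## Ensemble analysis conventions

The exact upstream RMSF/RMSD definitions are in an unavailable supplement,
so this package declares its own and applies them consistently: RMSD after
unweighted least-squares (Kabsch, proper rotation enforced; degenerate
collinear sets are an error) superposition of the fit selection, reported
over the report selection (supporting fit-on-whole/report-on-gate); RMSF per
window after superposing frames onto the window-mean structure (iterated
three times), RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ of the 3D displacement, so iid
per-axis jitter of s.d. σ gives σ√3. Residue selections accept hyphen or
en-dash ranges, deduplicate, and round-trip through a canonical string.

The gate fixture jitters 330 sites isotropically around a fixed helical
reference layout (σ = 0.5 Å per axis) and multiplies the gate sites'
(residues 96–106) s.d. by 3 in the later half of the windows, emulating the
destabilization of the gate as the ligand exits. It contains no correlated
motion, no rotation/translation drift, and no anisotropy — passing tests
show the analysis recovers constructed effects (amplification ratios, σ√3),
not that real trajectories behave this way.

## Kinetics

The primary fit is Lineweaver–Burk on replicate-*mean* rates (the source
plots show mean-based fits; the choice is recorded in the fit tag):
ordinary least squares of 1/v on 1/S, slope = Km/Vmax, intercept = 1/Vmax,
with a non-positive intercept treated as an error. Standard errors come
from the regression errors by the delta method. A direct nonlinear
least-squares fit of v = Vmax·S/(Km+S) (initialized from the LB fit, pooling
all replicate points) is the cross-check. Fixtures use 8 log-spaced
concentrations over 0.5–100 µM, 3 replicates (matching the reported
biological replication), and mean-one lognormal noise with CV = 2%; the
ground-truth parameter pairs carry the printed fold-changes exactly
(dimer/monomer Vmax 22, Km 1/5; tetramer/monomer Vmax 3.5, Km 1/10 — the
absolute values behind the published bar plots are graphical only, so the
fixtures encode the fold-changes, not absolutes). Over many seeds the
median fitted Vmax fold is within 5% of truth; single-seed fits scatter by
a few percent (Km folds somewhat more, since the double-reciprocal
transform amplifies low-concentration noise).

The Hill dose-response f(S) = Sⁿ/(Kⁿ+Sⁿ) (K½ = 5 µM, n = 1.5) and the
first-order activation time course m(t) = m∞(1 − e^(−t/τ)) (τ = 6 h) are
INVENTED phenomenological conveniences, labelled as such in their
docstrings and outputs: the defaults put activation onset below 10⁻⁶ M,
saturation near 10⁻⁴ M, and substantial activation only after ~8 h, but no
mechanistic mass-action model of multimerization is attempted.

## Numerical and degenerate-input choices

* Exchange with identical states or identical windows accepts with
  probability 1 (Δ = 0 handled without drawing).
* The 1D double-well test potential applies its tilt as a step at the
  barrier top so the half-line partition ratio is exactly e^(−ΔG/kT) at any
  temperature — the quadrature oracle then has an exact target. The price
  is a value discontinuity at the (measure-zero) barrier top.
* A single-window study is flagged `insufficient windows`: it still samples
  and reconstructs, but extracts no paths.
* MBAR raises on empty windows and on residuals above tolerance; WHAM flags
  empty bins and never interpolates them.
* Writers emit 17-significant-digit text and a declared row count; readers
  re-parse with exact round-tripping and fail loudly on missing columns or
  truncation.

## Known limitations

* The CV space *is* the configuration space here, so the PMF equals the
  potential; none of the orthogonal-degree-of-freedom averaging of a real
  PMF is exercised.
* Statistical uncertainties of the reconstructed landscape are reported
  only via the 75%-subset diagnostic; no bootstrap error bars are attempted
  (the upstream values carry none either).
* Branch labels rely on the two-minima geometry; surfaces with more basins
  need the unconstrained extractor.
* The kinetics fixtures assume multiplicative lognormal noise; heteroscedastic
  or additive-error data would favour weighted or direct NLS fits over
  Lineweaver–Burk.
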