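# Methods

## Model and units

The primitive model (PM) treats each ionic species as charged hard spheres
in a dielectric continuum: u_ij(r) is infinite inside the distance of
closest approach d_ij and Coulombic, q_i q_j e²/(4πε ε₀ r), outside. The
solvent enters only through the relative permittivity ε; the package default
is ε = 78.36 (pure water at 25 °C) and T = 298.15 K. Closest approaches are
additive, d_ij = (d_ii + d_jj)/2, as for hard spheres taken literally. The
sulfate-like anion diameter is fixed at d₋₋ = 4.6 Å throughout; the cation
diameter is the free parameter. Fractional charges (±1.5, ±1) express the
charge-scaled model variants obtained by multiplying every charge by a
constant factor.

Internal units: lengths in Å, charges in elementary charges, energies in
k_BT at the model temperature, dipole moments in debye (1 e·Å = 4.8032 D).
In these units βu_ij(r) = q_i q_j l_B/r with the Bjerrum length
l_B = e²/(4πε₀ ε k_B T) ≈ 7.1524 Å for the default model.

Molality is mapped to number density as ρ_i = ν_i m N_A ρ_w × 10⁻³⁰ Å⁻³
assuming a pure-water solvent of density ρ_w = 997.0 kg/m³ and zero solute
partial volume. This is the simplest defensible convention when the
experimental solution density is not part of the model; the constant is an
explicit, overridable argument. No McMillan–Mayer/Lewis–Randall scale
conversion is applied.

## HNC solver

The multicomponent Ornstein–Zernike equation ĥ = ĉ + ĉ ρ ĥ is closed with
HNC, g = exp(−βu + h − c), on a uniform radial grid r_k = (k+1)·dr
(default 2¹⁴ points, dr = 0.02 Å; minimum 2¹² points, dr ≤ 0.05 Å). Radial
Fourier transforms use the type-I discrete sine transform. A warning is
emitted when the grid extent is below 40 Debye lengths.

**Long-range handling.** The Coulomb tail is split with an error function at
κ_s = 1 Å⁻¹: βu = βu_short + q_i q_j l_B erf(κ_s r)/r. Iterating on the
renormalized variables c_s = c + βu_long and γ_s = h − c_s keeps every
transformed function absolutely integrable; the long-range part enters
Fourier space analytically as −4π l_B q_i q_j e^(−q²/4κ_s²)/q².

**Hard-core discretization.** Each radial bin carries a fractional
occupancy — zero inside the core, one outside, and the volume fraction of
the bin lying outside the core for the bin straddling contact. This makes
the discretized model vary smoothly as diameters change, which matters when
an optimizer sweeps d₊₊ continuously; a binary mask would make φ(d₊₊) a
staircase with steps of order 10⁻³.

**Iteration.** Damped Picard (initial mixing 0.1, slow growth, cap 0.3)
accelerated by Anderson/DIIS extrapolation (depth 5, damping 0.5) once the
residual is below 10. Safeguards: on blow-up the iteration restarts from the
best iterate with reduced mixing; if the best residual fails to halve over
150 iterations, Anderson is disabled for the rest of the attempt — near the
HNC solution boundary of 2:2 electrolytes Anderson oscillates where plain
damped Picard still converges. Convergence is max|Δγ_s| < 10⁻⁸; a solve that
does not converge raises an explicit error carrying the final residual,
never a silent result.

**Continuation.** A failed direct solve is retried by ramping all charges up
geometrically from 30% at the target density (8 steps), and as a last
resort by ramping densities geometrically from 1% of target (20 steps),
each converged state seeding the next. The charge ramp is attempted first
because it never crosses the dilute 2:2 regime where HNC is known to lose
solutions. An optional total-iteration budget bounds the cost of states
with no reachable solution.

**Zero-density limit.** States with fewer than ~10⁻³ particles expected in
the whole grid volume are returned analytically (h = c = Mayer f-function):
with nothing to screen the Coulomb tail, γ̂_s acquires a 1/q² singularity
whose discrete inverse transform carries a constant offset ∝ dq.

**Reliability diagnostic.** Every converged solution stores its worst
violation of the local-electroneutrality sum rule
Σ_j q_j ρ_j ∫ g_ij 4πr² dr = −q_i. Physical solutions satisfy it to ~10⁻⁹;
the spurious solutions that appear near the 2:2 HNC solution boundary
violate it at the 10⁻³ level or worse, so a threshold of 10⁻⁴ cleanly
separates them. The curve predictor treats solutions beyond the threshold
as failures.

**Thermodynamics.** The virial (pressure) route:
φ = 1 + (2π/3ρ) Σ_ij ρ_i ρ_j d_ij³ g_ij(d_ij⁺) + βE_el/3N, where the
Coulomb term is exact for a 1/r potential and
βE_el/N = (2π l_B/ρ) Σ_ij ρ_i ρ_j q_i q_j ∫ r h_ij dr. Contact values
g(d⁺) come from a 3-point parabolic extrapolation of the log cavity
function ln y = ln g + βu_Coul over the first three fully-open bins — y is
smooth across a charged contact where g itself rises exponentially. The
compressibility route is not implemented.

## Monte Carlo engine

Canonical Metropolis sampling with single-particle displacement moves,
acceptance min(1, e^(−βΔU)); hard-core overlaps are rejected outright.
Electrostatics use plain (non-mesh) Ewald summation under tin-foil boundary
conditions — adequate for the ≤ a few hundred particles used — with
α = 5.6/L, k_max = 8 and real-space cutoff L/2 by default. Reciprocal-space
structure factors are updated incrementally per move; the running energy is
compared against a full recomputation every 10⁴ moves (observed drift
≲ 10⁻¹⁴ relative). Initial configurations come from random sequential
insertion with overlap rejection (cap 10⁶ attempts). The inner loop is JIT
compiled; trajectories are bit-reproducible per seed on one platform.

Observables are block-averaged over 20 blocks: β-energy per particle, RDF
histograms per species pair (default bin width 0.05 Å), and φ per block via
the same virial expression as the HNC route. The MC contact value uses a
count-weighted *linear* fit of ln y over the first five bins outside the
core: on binned, noisy histograms the linear fit has substantially lower
extrapolation variance than a quadratic while the curvature bias stays well
below the statistical error at the run lengths used. Validation runs use 64
ion pairs (a deliberately larger box than the 12-pair polarizable-MD
system the model family mimics, to suppress finite-size error in the
oracle) and 2×10⁶ production moves.

## Cation-diameter fitting

`predict_curve` evaluates φ(m) by HNC at each requested molality, solving
from the most concentrated state downward with warm starts and bisecting
molality gaps on failure. Descending continuation keeps the solution on the
branch connected to the well-behaved concentrated regime; for small
cation–anion contact distances the dilute 2:2 states sit near the HNC
solution boundary where cold starts either fail or hop between multiple
fixed points. Points with no reliable solution (non-convergence or sum-rule
violation) are flagged NaN and dropped from the fit objective with a logged
warning — penalizing them would let the solver's convergence boundary steer
the optimizer. The radial grid is re-spaced per evaluation so that d₊₋
falls exactly on a node, removing the dominant residual discretization
sensitivity of φ to the fitted diameter.

`fit_cation_diameter` minimizes Σ_k w_k (φ_model(m_k) − φ_k)² with unit
weights (1/σ² when uncertainties are supplied) over d₊₊: a coarse scan
(default 0.25–0.5 Å steps over 1.5–6.5 Å) brackets the minimum, then
bounded scalar minimization refines it to 10⁻³ Å. The objective was scanned
and is unimodal over the tested range; φ at fixed molality increases
monotonically with d₊₊ (larger closest approach → weaker contact
attraction). Noiseless self-consistency recovery of planted diameters in
{2, 3, 4, 5} Å is exact to ≲ 4×10⁻⁴ Å on the 2¹² grid.

## Configuration statistics

Cubic periodic boxes with the minimum-image convention only. RDFs normalize
raw pair counts by the ideal-gas shell expectation (self-pairs excluded and
unordered pairs counted once for like species). Peak and minimum detection
smooths g(r) with a 5-point moving average; a local maximum counts as a
peak only if it exceeds the g = 1 baseline by at least 10% of the tallest
excess, so baseline bin noise does not register as structure. Peak
positions refine with a 3-point parabola on the raw curve; the CIP/SIP
minimum refines with a least-squares parabola over a 7-bin raw window,
which is markedly more noise-robust near a flat minimum. N_contact
integrates 4πρ_B g r² up to the CIP/SIP minimum when two peaks exist,
otherwise up to the first minimum after the first peak with an explicit
fallback flag.

CIP/SIP classification is purely radial (r < r_cip → CIP,
r_cip ≤ r < r_sip → SIP, per cation–anion pair, so one anion may be in
contact with several cations); no water-bridging topology is inspected, and
2SIP states are out of scope. Shell membership uses the 3.2 Å
metal–water-oxygen cutoff with set semantics (a water within the cutoff of
two cations is counted once). Δμ_ind averages dipole *magnitudes* of
in-shell waters minus all other waters, per frame, skipping frames where
either class is empty; waters in anion shells are not excluded from the
bulk class.

The point-polarizability energies are U = −(α/2)|E|² (always ≤ 0) and, for
a bare point charge, U = −α′q²/(4πε₀r⁴) with α′ the polarizability volume
in Å³. The two printed forms differ by exactly a factor of two when
E = q/(4πε₀r²) is substituted into the first; the package implements the
point-charge form verbatim and exposes the ½-consistent variant behind
`half_consistent=True` rather than guessing which convention was intended.
Reduced fields are expressed as q/r² (e/Å²) with
α_red = α′·e²/(4πε₀k_BT) so both forms return k_BT directly.

## Synthetic data

The generators produce static structural stand-ins for polarizable-MD
snapshots; there is no integrator, thermostat or replica-exchange engine.

* `gen_random_config`: uniform non-overlapping placement honoring all hard
  cores.
* `gen_paired_config`: plants an exact CIP/SIP census — n_cip cation–anion
  pairs at a prescribed contact distance, n_sip collinear
  cation–water–anion triplets with both bonds at the SIP gap distance — and
  disperses the remainder with all unplanned cation–anion distances beyond
  2.2× the SIP gap, so a radial classifier recovers the planted counts
  exactly. Optionally anions are rigid tetrahedra (central S plus four O at
  1.52 Å) in random orientations.
* `gen_dipole_field`: single-pass linear response — each water-like site
  receives μ = α′ E_perm from the minimum-image Coulomb field of the
  permanent ion charges, with no self-consistency between induced dipoles.
  This reproduces the superposition, q-linearity and 1/r² field structure
  that the Δμ_ind statistics probe, but not mutual polarization,
  saturation, or hydrogen-bond structure.
* `gen_osmotic_curve`: the HNC prediction for a known cation diameter plus
  i.i.d. Gaussian noise, standing in for measured osmotic-coefficient
  tables.

All generators are bit-deterministic per seed. Because the synthetic
configurations are idealized (point waters, planted geometries, no thermal
disorder beyond placement randomness), passing tests demonstrate the
correctness of the estimators and the internal consistency of the pipeline,
not the fidelity of any particular force field to real solutions.

## Validation problem sizes

The shipped validation suite solves HNC on 2¹²–2¹⁴-point grids, runs MC
with 64 ion pairs for 2×10⁶ production moves per state point (uncharged
reference runs: 200 spheres, 1–3×10⁶ moves), and performs the four
diameter-recovery fits on a 2¹² grid with five molalities in 0.1–2.0
mol/kg. These sizes make each check statistically decisive — MC standard
errors on φ of ~0.005 against tolerances of 0.01–0.03 — at a few minutes of
total runtime.

## Known limitations

* HNC for 2:2 electrolytes loses solutions in part of the dilute regime and
  develops multiple nearby fixed points close to that boundary; the package
  reports non-convergence explicitly, filters spurious solutions by the
  charge sum rule, and drops such points from fits rather than
  extrapolating through them.
* The virial route is the only φ route implemented; HNC's thermodynamic
  inconsistency means the compressibility route would differ at strong
  coupling.
* The MC oracle shares the virial contact-extrapolation step with the HNC
  route conceptually, but uses independent code paths and estimators; the
  agreement tolerance (0.03 in φ) absorbs both the HNC approximation error
  and residual estimator bias.
* Plain Ewald and O(N) per-move real-space sums limit the MC to small
  systems; that is sufficient for its role as a validation oracle.
* The molality→density conversion neglects solute volume; at 2 mol/kg this
  is a few-percent density approximation, applied consistently on both the
  generation and fitting sides.
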