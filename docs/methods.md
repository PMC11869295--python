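# Methods

This note documents the models implemented in `sookit`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that shape the results.

## Surrogate landscapes

The string and free-energy machinery operates on analytic 2D energy
surfaces over two proton-transfer coordinates (RC1, RC2, in Å), standing
in for quantum-chemical energy landscapes of proton-coupled electron
transfer (PCET). A surface is a sum of exponential-quadratic components
A·exp(dᵀMd) plus an optional harmonic confinement; energies are kcal/mol.

* `pcet-double-well` — two anisotropic wells at (−0.8, −0.8) and
  (+0.8, +0.8), elongated along the diagonal so their overlap carves a
  single interior saddle. The well depths and diagonal width are
  calibrated numerically at construction (nonlinear least squares against
  Newton-refined stationary points) so that three quantities are planted
  exactly: the minimum-energy-path barrier (default 12 kcal/mol), the
  reaction free energy (default +7.5 kcal/mol), and the height of the
  alternative route around the off-diagonal corner (+0.8, −0.8) (default
  15 kcal/mol). The defaults mirror the computed energetics of the
  favored stepwise PCET pathway versus its ~3 kcal/mol higher
  alternatives. The preset has exactly two minima and one saddle; the
  "alternative pathway" is a broad pass over the confined plateau, so a
  string initialized through the corner converges locally there without
  collapsing into the direct channel — mirroring the observation of
  multiple locally converged pathways.
* `mueller-brown` — the standard benchmark (three minima, two saddles),
  used to test saddle location on a surface two orders of magnitude
  stiffer than the PCET surrogate.
* `harmonic-well` — closed-form reference for sampler and estimator
  statistics.

Because the system has exactly the two coordinates that are biased and
histogrammed, the exact free-energy landscape equals the potential
surface; planted topography is therefore ground truth for every
estimator.

## Biased sampling

Restrained sampling uses overdamped-Langevin (Euler–Maruyama) proposals
x' = x − ∇V Δt + √(2k_BT Δt)ξ with a Metropolis correction (MALA). The
correction makes the stationary distribution exactly
exp(−(U + bias)/k_BT) at any stable step size, which the distributional
tests (χ² against direct quadrature of the biased density) require; plain
Euler–Maruyama only approaches that density as Δt → 0. The step size
defaults to 10⁻³ Å²·(kcal/mol)⁻¹ and is halved automatically for a window
after repeated energy overflows; unrecoverable divergence raises an error
carrying the offending step index. Chains start at the window center and
discard a 100-step burn-in. All randomness flows through explicit integer
seeds (PCG64); identical inputs give bit-identical streams. Temperature
is 310 K throughout (k_BT = 0.6160 kcal/mol, shared constant).

On stiff surfaces the biased density sits ≈ ∇U/k away from the restraint
center. `recenter_windows` corrects the centers (explicit first-order
shift plus damped fixed-point polish on the quadrature mean) so the
*sampled* distributions cover the intended points; the damping matters
because the naive iteration diverges wherever the surface curvature
exceeds the restraint stiffness.

## String method

A string is an ordered set of nodes (12 for concerted-style, 19 for
stepwise-style paths, configurable). Each iteration estimates per-node
drift as the biased-window mean minus the node (150 sampling steps per
window by default, k = 50–200 kcal mol⁻¹ Å⁻², with a warning outside that
range; a noise-free quadrature mode integrates the biased density
instead), refits a smooth curve through the drift-updated nodes — cubic
interpolating spline by default, quartic polynomial per coordinate as the
alternative (both give similar strings; the spline has smaller fitting
error on strongly curved paths) — and redistributes nodes to equal
arclength, each node located by bisection on the cumulative arclength of
a densely sampled curve (to ~10⁻¹⁴ in parameter, comfortably below the
10⁻⁶ relative-arclength contract). Endpoints are pinned by default (the
reactant and product basins are known); a free-endpoint mode simply
leaves endpoint drift unprojected. Convergence is declared when both the
sum of squared node displacements and the maximum squared displacement
between consecutive strings stay below 0.008 and 0.05 Å² for at least
three consecutive iterations; both thresholds are interpreted as squared
displacements, in the units they are conventionally quoted.

At finite restraint stiffness the fixed point of the drift iteration
deviates from the true minimum-energy path by roughly (H + K)⁻¹∇U, where
H is the surface Hessian. On the PCET surrogate (|H| ≈ 30–60) the
standard k = 200 is ample; on the Müller–Brown benchmark (|H| up to
~4×10³) the tests use k = 1000, which brings the converged string within
0.05 units of both saddles.

## Free-energy reconstruction

Three estimators consume the same biased windows and a shared output
grid (default 100×100 over the sampled range padded 5%; bins with fewer
than 10 samples are flagged unoccupied and reported as NaN, never zero;
the minimum occupied bin defines F = 0):

* **WHAM** — self-consistent histogram estimate. The per-window bias
  Boltzmann factor is averaged analytically over each bin (Gaussian mass
  via erf) rather than evaluated at the bin center. Window free energies
  are first obtained by L-BFGS on the convex WHAM likelihood, then
  polished by direct iteration to the stated tolerance (10⁻⁷ kcal/mol).
* **MBAR** — the multistate Bennett acceptance ratio on per-sample bias
  energies, solved by damped Newton iterations with the exact Hessian and
  a self-consistent fallback; the unbiased per-sample weights are then
  histogrammed. When the bias-energy matrix would be very large, sample
  positions are quantized onto a grid five times finer than the output
  bins and carried with multiplicities — the equations are unchanged and
  the quantization error is far below the bin resolution.
* **Variational profile** — direct maximum-likelihood estimation of the
  free-energy field given the binned samples, optionally parameterized on
  a coarser bilinear control grid (an under-determined basis is
  rejected). With the default (one parameter per occupied bin) its
  optimum coincides with the WHAM fixed point, providing an independent
  route to the same estimate; a coarse basis gives a smoothed field.

The default bin count is 100 per axis: at the standard restraint
stiffness (k = 200, window σ ≈ 0.055 Å) this keeps the bin width near
σ/2. Coarser grids (e.g. 50) make the within-bin variation of the bias
factor comparable to k_BT, which biases histogram estimates by several
tenths of a kcal/mol at a 12 kcal/mol barrier and degrades agreement with
the per-sample estimator. For steeper surfaces WHAM and the variational
profile additionally solve on an internally refined grid (`refine`,
default 2) and aggregate the Boltzmann weights back to the output bins;
matching this refinement with MBAR's quantization grid makes all three
estimators consistent to ≲0.16 kcal/mol binwise even on the Müller–Brown
benchmark.

Path barriers interpolate the landscape bilinearly along the densely
sampled fitted string; the reactant (product) reference is the lowest
occupied bin within 0.3 Å of the first (last) path point. Uncertainties
come from a block bootstrap: contiguous sample blocks (default 10 per
window) resampled with replacement, the estimator re-run per replicate.
The umbrella-grid builder reproduces the 13×13/169-window protocol with
its 200 kcal mol⁻¹ Å⁻² default; per-window sampling defaults to 1000
steps, the 1 ps-per-window budget at a 1 fs step (the source protocol's
total-sampling figures are internally inconsistent, so per-window length
is configuration).

## Rates and thermodynamics

The Moser–Dutton ruler is used in its standard exergonic form
log₁₀k = 13 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(ΔG + λ)²/λ, with the same
quadratic Marcus term on the endergonic branch; it reproduces the quoted
800 s⁻¹ (17 Å, ΔG = 0), ~10⁷ s⁻¹ (9 Å) and ~100 ns interheme (11 Å,
−0.108 eV) figures with λ = 0.7 eV, ρ = 0.76. TST uses k₀ = 6 ps⁻¹ and
neglects recrossing; rate and barrier conversions are exact inverses.
Nernst shifts use E = E_m − 59 mV·log₁₀([red]/[ox]) — the sign such that
depleting the reduced species raises the potential, which matches the
worked ~+80 mV upshift of the O₂/O₂•⁻ couple at [O₂•⁻] = 10⁻¹⁰ M,
[O₂] = 10⁻⁶ M (a printed formula with the opposite sign appears in the
source; the worked number is followed). The 59 mV/decade slope is used
verbatim (not RT·ln10/F at 310 K = 61.5 mV) and is configurable. Driving
forces are ΔG = −nF(E_acc − E_don) with F = 23.061 kcal mol⁻¹ V⁻¹.

## Kinetic model

States enumerate (heme 2 ox/red) × (heme 1 ox/red) × (Q, Q•⁻, QH₂) — 12
states. Transitions: superoxide delivery in series with the 9 Å
tunneling step (delivery is pseudo-first-order, default 10⁸ s⁻¹ — the
value used upstream is unpublished, making this the model's main free
knob; turnover is therefore treated as an order-of-magnitude quantity),
interheme transfer (11 Å), first Q reduction (6 Å), and the final PCET
(TST of the computed barrier), which is irreversible to represent quinol
unbinding. Every other transition gets its reverse rate from detailed
balance, k_f/k_r = exp(−ΔG/k_BT), audited at construction. Integration
uses a stiff BDF solver with the exact constant Jacobian at tight
tolerances; probability conservation is enforced to 10⁻⁸ and the
solution is tested against the matrix-exponential propagator to 10⁻⁶.
t_½ is located by linear interpolation on a dense log-spaced output grid
(default 10⁴ points) and turnover is ln 2/t_½. With the printed
distances, potentials and a 12 kcal/mol PCET barrier the model gives
turnover ~1.6×10⁴ s⁻¹ with μs-scale quinol formation, the final PCET
being >100× slower than the interheme step.

## Synthetic trajectories

The fixture generators plant known values of exactly the statistics the
ensemble module measures: a piecewise-uniform axial density with a
chosen core/bulk ratio (default 12), a Gaussian radial shell at a chosen
RDF peak (9 Å), a Bernoulli site-dwell fraction (40%), and a telegraph
bound/unbound distance signal with exact switch points. They emulate the
*distributional* signatures of membrane simulations — partitioning,
clustering, transient binding — with independent frames; they have no
dynamics, interactions, or realistic correlation structure, so passing
tests demonstrate estimator correctness, not force-field realism.
Occupancies are reported under both conventions (fraction of frames with
any particle in the site, and mean fraction of particles in the site),
since either reading appears in practice. Minimum-image distances assume
orthorhombic boxes.

## Orchestration

`RunConfig` is a strict JSON schema (unknown keys rejected; all
violations reported together). The global seed is split via
`numpy.random.SeedSequence` into per-stage child seeds; identical
configurations reproduce identical output checksums (SHA-256, recorded
in the run manifest). The default pipeline — 19-node string with sampled
drift, 1000 samples per window along the converged string, all three
estimators, the printed rate parameters — completes in a few seconds on
one CPU. Test problem sizes (5000 samples/window, tens of windows,
10–40 bootstrap replicates) were chosen to give sub-0.5 kcal/mol
statistical resolution at interactive runtimes.

## Known limitations

* Strings are 2D (reaction-coordinate space); no Cartesian or
  higher-dimensional paths.
* The finite-stiffness bias of the string fixed point is not corrected;
  use stiffer restraints (or the quadrature drift mode) on surfaces whose
  curvature approaches the restraint constant.
* Block bootstrap is the only uncertainty model; no autocorrelation-based
  statistical-inefficiency estimates.
* The kinetic model's superoxide-delivery rate is a free parameter; only
  order-of-magnitude turnover comparisons are meaningful.
* The occupied-bin convention censors sparsely sampled regions; barrier
  paths must stay within sampled territory or an error is raised.
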