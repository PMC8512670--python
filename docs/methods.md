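# Methods

## Scope and model

The package computes structural, dynamical and spectroscopic observables
of a single-ion hydration shell from MD-style trajectories (one cation
plus waters in a periodic cubic box), and provides a stochastic generator
whose trajectories have *known* ground truth, so that every estimator is
validated by parameter recovery rather than against an irreproducible
simulation.  Units are fixed globally: Å, ps, kcal/mol, Debye, eV.

All distances use the minimum-image convention in a cubic box.
Coordinates are stored unwrapped; dynamics (MSD) use the unwrapped ion
path, structure wraps on demand.  Shell membership for structural
quantities is instantaneous (oxygen within the cutoff); hysteresis exists
only in the residence-time analysis through the excursion tolerance t\*.

## Synthetic trajectories

The generator factorizes the statistics of a hydrated-ion trajectory into
independently controlled components:

- **Radial structure.**  First- and second-shell ion–O distances follow
  Ornstein–Uhlenbeck processes with stationary mean μ and variance σ²
  (relaxation times 0.2 / 0.5 ps — fast enough that 10⁴ frames give an
  effectively exhaustive sample, slow enough to be resolved at the 0.1 ps
  sampling interval).  Since the reported shell radii are RDF *modes* and
  g(r) ∝ P(r)/r², the OU mean carries the Jacobian correction
  μ = r_peak + 2σ²/r_peak so the g(r) maximum lands on the requested peak.
  The pooled first-shell distance variance is exactly the requested σ²,
  which is the Debye–Waller second cumulant.
- **Occupancy.**  The coordination number follows a continuous-time
  birth–death Markov chain with a prescribed stationary law; death rates
  are rescaled so the stationary total leave rate equals ⟨CN⟩/τ_res, which
  pins the mean residence time, and birth rates follow from detailed
  balance.  By default the per-molecule leave hazard is uniform (d_n ∝ n),
  making residence episodes exponential with mean τ_res; the cation
  presets instead weight deaths toward the high-CN states so that minority
  hydrates are short-lived, as observed.  A death moves a member to the
  second shell; a birth promotes a second-shell molecule with a fresh
  stationary radius.  Exchange events are simulated exactly (Gillespie)
  and snapped to the frame grid; a molecule never leaves and re-enters
  within a single frame, so every logged event is observable.
- **Flickers.**  Brief excursions — a member parking just outside the
  shell, or an outer molecule briefly entering — are generated separately
  from exchanges at a Poisson rate, with exponential durations (mean
  0.5 ps, rounded up to at least one frame).  They are what separates
  MRT(t\*=0) from MRT(t\*=2): presets use τ_res = MRT(t\*=2) and
  flicker rate = ⟨CN⟩·(1/MRT₀ − 1/MRT₂).
- **Geometry on the sphere.**  Member directions diffuse tangentially and
  are re-centred each frame (Σu ≈ 0), with a weak soft repulsion between
  members; the centring removes the spurious shell-COM wander a random
  walk would produce.  The hydrate eccentricity is imposed explicitly: a
  per-frame isotropic Gaussian offset vector c (scaled so E|c| equals the
  requested ϵ after deflating for the irreducible 1/N shell-COM noise) is
  realized by tilting all member directions by a common small vector,
  solved against the realized direction second moment — this moves the
  shell COM without touching the radial distances.
- **Orientations.**  Each water carries a bisector/H–H frame.  The frame
  is transported with its member's angular motion (twist-free), given
  explicit spin diffusion about the radial axis, and its tilt angle
  relaxes by an OU process toward the preset wrapped-Gaussian law.
  Transport + spin together realize isotropic rotational diffusion with
  coefficient d_rot = 1/(6 τ₂,μ), so the fitted second-order dipole
  reorientation time recovers the preset value and τ₁/τ₂ → 3 (the
  tangential step is inflated by 1/(1 − 1/⟨CN⟩) to undo the variance the
  centring projection removes).  Consequence of one d_rot: the generator
  cannot match a preset's τ₁ and τ₂ independently; presets pin τ₂.
- **Ion.**  Discrete Brownian motion with the preset D
  (1 Å²/ps = 10·10⁻⁵ cm²/s).
- **Bulk.**  Ideal-gas filler waters with random orientations, placed
  uniformly outside the second shell each frame; total water count fills
  the box to the experimental density (0.997 g/cm³).  No water–water
  structure is modelled — bulk exists for density normalization and the
  far M–H background only, so g(r) sits slightly below 1 between the
  second shell and the exclusion radius.

### Preset parameters not taken from published values

Desk scale: box edge 14 Å (~91 waters) rather than a production-size box —
no recovered quantity depends on the bulk population beyond its density —
and 10⁴ frames at Δt = 0.1 ps (1 ns span).  The second-shell radial
spread (0.24–0.28 Å), the bound that second-shell waters do not point
hydrogens into the inter-shell gap (tilt ≥ 90°, H–H axis near-tangential
with 5° spread), and the flicker excursion distance (mid-gap) were fixed
once, by forward calculation, so that the synthetic M–H profile reproduces
the reported inter-shell boundary (M–H first minimum) of the hydrated ion;
realized second-shell tilt statistics are therefore a few degrees narrower
than the nominal preset numbers.  Bulk dipole magnitude is 2.95 D with a
0.3 D spread.

### What the generator does not emulate

Anharmonic (skewed) distance distributions, water–water correlations,
hydrogen-bond network dynamics, transit paths during exchanges
(instantaneous swaps), and coupled τ₁/τ₂ anisotropy.  Passing recovery
tests therefore demonstrates estimator correctness under a faithful but
idealized statistical model, not force-field realism.

## Estimators

- **RDF.** Histogram with Δr = 0.02 Å by default (reported radii carry
  two decimals, so bins must not exceed 0.02 Å); g = counts/(4πr²Δr ρ F);
  n(r) is the exact cumulative per-frame neighbour count (algebraically
  the midpoint-rule integral of g r²).
- **First minimum.** 5-bin moving average, lowest smoothed value in the
  search window (defaults to the span between the first two detected
  peaks), ties toward smaller r; interior-minimum required, monotone
  profiles raise.
- **Second cumulant.** Population variance of the pooled first-shell
  distance sample over molecules and frames (per-molecule averaging would
  weight members unevenly under exchanges).
- **Eccentricity.** Full atomic masses (O 15.999, H 1.008); hydrogens ride
  with their oxygen across periodic images.  Empty-shell frames are
  excluded and counted.
- **MRT.** Direct event-counting method: membership columns are annealed
  symmetrically (outbound gaps and inbound blips shorter than t\* are
  removed — the convention is symmetric because only excursions, not their
  sign, are below the resolution of interest), then
  MRT = ⟨CN⟩·T/N_leave with N_leave the annealed intervals ending before
  the final frame.  Uncertainty: standard error over 4 time blocks (block
  count configurable).  No accepted event ⇒ censored, MRT reported as the
  lower bound T.  The intermittent survival correlation is provided as a
  cross-check, not the headline.
- **Reorientation.** C_i over time origins and molecules that are shell
  members at both ends of the lag (continuous-membership selection would
  be stricter but starves statistics; endpoint selection is unbiased here
  because orientations persist through brief excursions).  τ from a
  log-linear fit over 2–20 ps by default, excluding sub-ps libration;
  non-positive C inside the window raises with diagnostics; no measurable
  decay returns τ = ∞ flagged frozen.
- **Diffusion.** FFT multi-origin MSD; weighted slope fit over the window
  (default 10–100 ps).  Var[MSD(τ)] grows ∝ τ³ for overlapped estimates
  and neighbouring lags are strongly correlated, so weights are steepened
  to 1/τ⁴ and the default fit runs through the origin (a diffusive MSD has
  none; an intercept option exists for data with short-time structure).
- **MEE removal.** On k²χ over [0, 10] Å⁻¹: a curvature-penalized cubic
  B-spline (knots every 0.25 Å⁻¹ — able to follow the structural
  oscillation, too stiff for a narrow anomaly) is fitted jointly with a
  parametric anomaly (Gaussian + error-function step on the χ scale,
  centre constrained to the search region, width 0.05–0.6 Å⁻¹), the
  penalty included in the optimizer's objective.  The anomaly is accepted
  only if it halves the in-region misfit (cost ratio ≥ 2) and its centre
  is not pinned to the region edge; otherwise the input is returned
  unchanged with a warning.  The subtraction is tapered to exactly zero
  beyond region ± 2 Å⁻¹.  Validation is by injection–recovery; the exact
  published background procedures are not reproducible from their
  descriptions, so this reconstruction is the package's own defined
  procedure.
- **EXAFS averaging/FT.** Per-snapshot σ² = 0; disorder enters through the
  configurational average, which reproduces the cumulant form
  exp(−2σ²k²) with its first-order phase shift −4σ²k(1/R + 1/λ) for
  Gaussian disorder.  FT: Hann (default) or Kaiser window on a uniform,
  zero-padded grid; χ̃(R) = (1/√π)∫χ(k)Ω(k)e^{2ikR}dk; R-spacing
  π/k_max,padded; magnitudes scale with the window's coherent gain, and
  peak positions are independent of padding beyond 2×.
- **ΔE₀.** k′ = √(k² − 0.262468·ΔE₀), cubic re-interpolation onto the
  original grid, out-of-support points dropped.

## Numerical/degenerate-input choices

Zero-length bisectors are skipped with a warning (tilt); empty shells
raise domain errors; k = 0 is excluded from χ grids (1/k pole); double
k-weighting is a state error; tilt angles are clipped away from the poles
by 0.5° in the generator to keep rotation axes defined.  Because tilt has
bounded support, a wide nominal spread (e.g. 38°) yields a realized mean a
few degrees below the nominal value — negligible for narrow spreads.

## Known limitations

The first-minimum position on near-empty inter-shell valleys is resolved
only to a few bin widths (ties break left); the MRT block uncertainty is a
convention, not an exact error; the diffusion fit's formal error
understates the true scatter (~10% at 10⁴ frames) because lag correlations
survive the weighting; wide MEE anomalies at high k recover less precisely
than the narrow canonical case; the CLI's `analyze` regenerates synthetic
trajectories rather than caching them.
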