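# hydrashell

Hydration-shell structure and dynamics of heavy alkaline-earth cations
(Sr²⁺, Ba²⁺, Ra²⁺) in water, with snapshot-averaged EXAFS construction —
a reusable analysis pipeline for ion-in-water MD trajectories plus a
synthetic-trajectory generator that makes every estimator verifiable by
parameter recovery.

## Who this is for

Simulators and spectroscopists who have (or want to emulate) a classical MD
trajectory of one ion in water and need the standard battery of
hydration-shell observables:

- **structure** — ion–oxygen / ion–hydrogen radial distribution functions
  g(r) with running integration numbers n(r), shell cutoffs from RDF
  minima, coordination-number histograms, the second cumulant
  σ² = ⟨(R−⟨R⟩)²⟩ of the first-shell ion–O distance (the EXAFS
  Debye–Waller factor), the water tilt angle (bisector vs O→ion; 180° is
  the ideal ion–dipole orientation), the hydrate eccentricity
  ϵ = ⟨|r_ion − r_COM(shell)|⟩ and the shell-induced dipole increment Δμ;
- **dynamics** — water-exchange mean residence times by the direct
  event-counting method, MRT = ⟨CN⟩·T / N_leave, with an excursion
  tolerance t\* that anneals brief departures and entries; lifetimes of
  constant-coordination episodes; reorientational correlation times τ_i
  from C_i(t) = ⟨P_i(u(0)·u(t))⟩ for the dipole, H–H, O–H and
  plane-normal axes; the ion self-diffusion coefficient from the Einstein
  relation D = slope(MSD)/6;
- **EXAFS** — the single-scattering path sum
  χ(k) = S₀² Σ_j N_j/(kR_j²) f(k) e^(−2R_j/λ(k)) sin(2kR_j + φ(k)),
  evaluated per MD snapshot at instantaneous distances and averaged so
  thermal disorder enters configurationally; k-weighting, ΔE₀ energy-origin
  alignment, windowed Fourier transforms to R-space, and removal of
  multielectron-excitation (MEE) anomalies by a penalized-spline +
  peak/step fit validated by injection–recovery.

Scattering amplitudes/phases are pluggable (FEFF path-table dialect or a
parametric model); multiple scattering and XANES are out of scope.

## Worked example

```python
from hydrashell import (preset, gen_shell_trajectory, compute_rdf,
                        find_first_minimum, coordination_number,
                        second_cumulant, mean_residence_time)

traj, truth = gen_shell_trajectory(preset("Sr2+", n_frames=10_000, seed=1))
rdf = compute_rdf(traj, "M-O", dr=0.02)
r_cut = find_first_minimum(rdf)
print(f"R(M-O)  = {rdf.r[rdf.g.argmax()]:.2f} Å")
print(f"r_cut   = {r_cut:.2f} Å")
print(f"CN      = {coordination_number(rdf, r_cut):.2f}")
print(f"DW      = {second_cumulant(traj, r_cut):.4f} Å²")
res = mean_residence_time(traj, r_cut, t_star=2.0)
print(f"MRT(2)  = {res.mrt:.0f} ± {res.uncertainty:.0f} ps "
      f"({res.n_events} exchanges)")
```

prints

```
R(M-O)  = 2.55 Å
r_cut   = 3.23 Å
CN      = 8.15
DW      = 0.0170 Å²
MRT(2)  = 86 ± 2 ps (95 exchanges)
```

i.e. the Sr²⁺ aqua ion of the preset is recovered: first-shell peak at
2.57 ± 0.02 Å (bin-width resolution), ~8.1 first-shell waters inside the
auto-detected cutoff, a Debye–Waller variance of 0.017 Å², and a residence
time around 90 ps once sub-2-ps flickers are annealed (65 ps counting
every excursion).  `truth` carries the exact generator parameters and
exchange-event log the estimates can be audited against.

The numbered drivers under `analysis/` run the full study — generation
(`01`), the structural table (`02`), the dynamics table (`03`), the
averaged EXAFS spectra and their R-space transforms (`04`) and the MEE
injection–recovery demonstration (`05`) — writing their tables under
`results/`.  The `hydrashell` command exposes the same steps as
subcommands (`synth`, `analyze`, `exafs`, `mee`, `report`).

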