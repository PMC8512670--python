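"""Structural observables of an ion hydration shell.

Radial distribution functions with running coordination numbers, the
hydrate coordination-number histogram, the second cumulant (Debye–Waller
variance) of the first-shell ion–oxygen distance, the water tilt angle, the
hydrate eccentricity and the shell-induced dipole increment.

Shell membership is instantaneous here (a molecule is in the shell whenever
its minimum-image ion–oxygen distance is below the cutoff); hysteresis via
the excursion tolerance t* belongs to the dynamics module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .core import MASS_H, MASS_O, MASS_WATER, Trajectory, minimum_image
from .errors import CapabilityError, DomainError, NoMinimumError

__all__ = [
    "RDFProfile",
    "CNHistogram",
    "TiltStats",
    "EccentricityStats",
    "DipoleIncrement",
    "compute_rdf",
    "find_first_minimum",
    "coordination_number",
    "cn_histogram",
    "second_cumulant",
    "tilt_angles",
    "eccentricity",
    "induced_dipole",
    "shell_mask",
]


@dataclass
class RDFProfile:
    """g(r) on uniform bins with its running integration number n(r).

    ``n`` is cumulative at the *right edge* of each bin, i.e. ``n[i]`` counts
    the average number of neighbours within ``r[i] + dr/2``.
    """

    r: np.ndarray          # bin centers (Å)
    g: np.ndarray
    n: np.ndarray
    pair: str              # "M-O" or "M-H"
    rho: float             # number density used for normalization (Å^-3)
    dr: float

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if np.any(np.diff(self.n) < -1e-12) or (self.n.size and self.n[0] < 0):
            raise ValueError("running integration number must be non-decreasing")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"r": self.r, "g": self.g, "n": self.n})


@dataclass
class CNHistogram:
    """Occupancy fraction of each instantaneous coordination number."""

    fractions: dict[int, float]
    r_cut: float

    def __post_init__(self) -> None:
        tot = sum(self.fractions.values())
        if self.fractions and not np.isclose(tot, 1.0):
            raise ValueError("occupancy fractions must sum to 1")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("occupancy fractions must be non-negative")

    @property
    def mode(self) -> int:
        return max(self.fractions, key=self.fractions.get)

    @property
    def mean(self) -> float:
        return sum(n * p for n, p in self.fractions.items())


@dataclass
class TiltStats:
    mean: float
    sd: float
    n_samples: int
    histogram: tuple[np.ndarray, np.ndarray] | None = None  # (edges, density)


@dataclass
class EccentricityStats:
    mean: float
    sd: float
    n_frames: int
    n_empty: int = 0


@dataclass
class DipoleIncrement:
    """Mean |dipole| excess of shell waters over bulk waters, per shell (D)."""

    dmu: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)


def shell_mask(traj: Trajectory, r_cut: float,
               r_lo: float = 0.0) -> np.ndarray:
    """Boolean (F, N) mask of instantaneous shell membership."""
    d = traj.oxygen_distances()
    return (d < r_cut) & (d >= r_lo)


def compute_rdf(
    traj: Trajectory,
    pair: str = "M-O",
    dr: float = 0.02,
    r_max: float | None = None,
) -> RDFProfile:
    """Ion–oxygen or ion–hydrogen radial distribution function.

    g(r) = ⟨histogram⟩ / (4π r² Δr ρ) with minimum-image distances, where ρ
    is the number density of the partner species (oxygens, or hydrogens at
    twice the molecular density).  The running integration number is the
    exact per-frame neighbour count, n(r) = 4πρ ∫₀ʳ g(s) s² ds.
    """
    if r_max is None:
        r_max = min(10.0, traj.box / 2.0)
    if r_max > traj.box / 2.0 + 1e-9:
        raise DomainError(
            f"r_max={r_max} Å exceeds half the box edge {traj.box / 2:.2f} Å"
        )
    if pair == "M-O":
        dist = traj.oxygen_distances().ravel()
        n_partner = traj.n_waters
    elif pair == "M-H":
        dist = traj.hydrogen_distances().ravel()
        n_partner = 2 * traj.n_waters
    else:
        raise DomainError(f"unknown pair {pair!r}; use 'M-O' or 'M-H'")
    nbins = int(round(r_max / dr))
    counts, edges = np.histogram(dist, bins=nbins, range=(0.0, nbins * dr))
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = n_partner / traj.box ** 3
    shell_vol = 4.0 * np.pi * centers ** 2 * dr
    g = counts / (traj.n_frames * shell_vol * rho)
    n_run = np.cumsum(counts) / traj.n_frames
    return RDFProfile(centers, g, n_run, pair, rho, dr)


def _smooth(g: np.ndarray, width: int = 5) -> np.ndarray:
    return uniform_filter1d(g.astype(float), size=width, mode="nearest")


def find_first_minimum(
    rdf: RDFProfile,
    window: tuple[float, float] | None = None,
    smooth_bins: int = 5,
) -> float:
    """Position of the first inter-shell minimum of a radial profile.

    The profile is smoothed with a moving average (default 5 bins) and the
    lowest smoothed value between the first and second maxima is returned;
    ties break toward smaller r.  ``window`` restricts the search range
    (defaults to the span between the global maximum and the next detected
    peak).

    Raises :class:`NoMinimumError` when the profile has no interior minimum
    in the search range (e.g. a monotone profile).
    """
    s = _smooth(rdf.g, smooth_bins)
    if window is None:
        imax = int(np.argmax(s))
        later, _ = find_peaks(s[imax + 1:], prominence=0.02 * float(s.max()))
        ihi = imax + 1 + int(later[0]) if later.size else s.size - 1
        lo_idx, hi_idx = imax, ihi
    else:
        lo, hi = window
        idx = np.flatnonzero((rdf.r >= lo) & (rdf.r <= hi))
        if idx.size < 3:
            raise NoMinimumError("search window contains fewer than 3 bins")
        lo_idx, hi_idx = int(idx[0]), int(idx[-1])
    seg = s[lo_idx:hi_idx + 1]
    im = int(np.argmin(seg))  # argmin takes the first occurrence: smaller r
    if im == 0 or im == seg.size - 1:
        raise NoMinimumError(
            "no interior minimum in the search range (monotone profile?)"
        )
    return float(rdf.r[lo_idx + im])


def coordination_number(rdf: RDFProfile, r_cut: float) -> float:
    """Running integration number n(r) evaluated at ``r_cut``."""
    edges = rdf.r + rdf.dr / 2.0
    if not (0.0 <= r_cut <= edges[-1] + 1e-9):
        raise DomainError(f"r_cut={r_cut} outside the profile grid")
    return float(np.interp(r_cut, np.concatenate(([0.0], edges)),
                           np.concatenate(([0.0], rdf.n))))


def cn_histogram(traj: Trajectory, r_cut: float) -> CNHistogram:
    """Fraction of frames spent at each instantaneous coordination number."""
    cn = shell_mask(traj, r_cut).sum(axis=1)
    vals, counts = np.unique(cn, return_counts=True)
    frac = {int(v): float(c) / traj.n_frames for v, c in zip(vals, counts)}
    return CNHistogram(frac, r_cut)


def second_cumulant(traj: Trajectory, r_cut: float) -> float:
    """Second cumulant σ² of the pooled first-shell ion–oxygen distances (Å²).

    This is the population variance ⟨(R − ⟨R⟩)²⟩ of every first-shell
    distance sample over every frame — the quantity identified with the
    EXAFS Debye–Waller factor.
    """
    d = traj.oxygen_distances()
    sample = d[d < r_cut]
    if sample.size == 0:
        raise DomainError("first shell is empty throughout the trajectory")
    return float(np.var(sample))


def tilt_angles(
    traj: Trajectory,
    r_cut: float,
    r_lo: float = 0.0,
    bins: int = 36,
) -> TiltStats:
    """Tilt of shell waters: angle between the molecular bisector
    (O → H-midpoint) and the O → ion vector, pooled over molecules and
    frames.  180° is the ideal ion–dipole orientation for a cation.
    ``r_lo`` > 0 selects an outer shell (r_lo ≤ r < r_cut).
    """
    mask = shell_mask(traj, r_cut, r_lo)
    if not mask.any():
        raise DomainError("first shell is empty throughout the trajectory")
    bis = 0.5 * (traj.h_pos[:, :, 0, :] + traj.h_pos[:, :, 1, :]) - traj.o_pos
    to_ion = minimum_image(traj.ion_pos[:, None, :] - traj.o_pos, traj.box)
    bn = np.linalg.norm(bis, axis=-1)
    tn = np.linalg.norm(to_ion, axis=-1)
    degenerate = mask & (bn < 1e-10)
    if degenerate.any():
        warnings.warn(
            f"skipping {int(degenerate.sum())} degenerate (zero-length) "
            "bisectors", stacklevel=2)
        mask = mask & ~degenerate
    cosang = np.sum(bis * to_ion, axis=-1) / np.maximum(bn * tn, 1e-300)
    ang = np.degrees(np.arccos(np.clip(cosang[mask], -1.0, 1.0)))
    hist, edges = np.histogram(ang, bins=bins, range=(0.0, 180.0),
                               density=True)
    return TiltStats(float(ang.mean()), float(ang.std()), int(ang.size),
                     (edges, hist))


def eccentricity(traj: Trajectory, r_cut: float) -> EccentricityStats:
    """Mean distance between the ion and the first-shell centre of mass.

    The centre of mass uses full atomic masses (O 15.999, H 1.008).  Frames
    with an empty shell are excluded and counted.
    """
    mask = shell_mask(traj, r_cut)
    occup = mask.sum(axis=1)
    good = occup > 0
    n_empty = int((~good).sum())
    if not good.any():
        raise DomainError("first shell is empty throughout the trajectory")
    if n_empty:
        warnings.warn(f"{n_empty} frames with an empty first shell excluded",
                      stacklevel=2)
    d_o = minimum_image(traj.o_pos - traj.ion_pos[:, None, :], traj.box)
    # hydrogens ride with their oxygen: intramolecular vectors are not wrapped
    d_h = d_o[:, :, None, :] + (traj.h_pos - traj.o_pos[:, :, None, :])
    w = mask[..., None].astype(float)
    num = (MASS_O * (d_o * w).sum(axis=1)
           + MASS_H * (d_h * w[:, :, None, :]).sum(axis=(1, 2)))
    com = num[good] / (MASS_WATER * occup[good, None])
    eps = np.linalg.norm(com, axis=1)
    return EccentricityStats(float(eps.mean()), float(eps.std()),
                             int(good.sum()), n_empty)


def induced_dipole(
    traj: Trajectory,
    cutoffs: tuple[float, float],
) -> DipoleIncrement:
    """Shell-induced dipole increment Δμ per hydration shell (Debye).

    Δμ(shell) = mean |μ| of shell members − mean |μ| of bulk members, where
    the first shell is r < cutoffs[0], the second shell cutoffs[0] ≤ r <
    cutoffs[1] and the bulk r ≥ cutoffs[1].
    """
    if traj.dipoles is None:
        raise CapabilityError("trajectory carries no dipole vectors")
    r1, r2 = cutoffs
    if not (0 < r1 < r2):
        raise DomainError("cutoffs must satisfy 0 < r1 < r2")
    d = traj.oxygen_distances()
    mag = np.linalg.norm(traj.dipoles, axis=-1)
    m1 = d < r1
    m2 = (d >= r1) & (d < r2)
    mb = d >= r2
    if not mb.any():
        raise CapabilityError("no bulk molecules beyond the second cutoff")
    mu_bulk = float(mag[mb].mean())
    out = DipoleIncrement()
    for name, m in (("I", m1), ("II", m2)):
        if m.any():
            out.dmu[name] = float(mag[m].mean()) - mu_bulk
            out.sd[name] = float(np.sqrt(mag[m].var() + mag[mb].var()))
    return out
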