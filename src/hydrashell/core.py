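"""Core domain types for ion-in-water trajectory analysis.

Units are fixed globally across the package: Ångström for lengths,
picoseconds for times, kcal/mol for energies, Debye for dipole moments and
eV for spectral energy shifts.

The in-memory trajectory container is array-backed for speed: a
:class:`Trajectory` stores contiguous ``(n_frames, n_waters, ...)`` numpy
arrays, while :class:`Frame` and :class:`WaterMolecule` give the per-snapshot
object view used by I/O and small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "MASS_O",
    "MASS_H",
    "MASS_WATER",
    "WaterMolecule",
    "Frame",
    "Trajectory",
    "EnergyBreakdown",
    "SpectrumK",
    "interaction_energy",
    "minimum_image",
]

MASS_O = 15.999
MASS_H = 1.008
MASS_WATER = MASS_O + 2.0 * MASS_H

_TIME_TOL = 1e-9  # ps; allowed jitter in frame spacing


def minimum_image(vec: np.ndarray, box: float) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    vec : array, shape (..., 3)
        Raw displacement vectors.
    box : float
        Cubic box edge length (Å).
    """
    return vec - box * np.round(vec / box)


@dataclass
class WaterMolecule:
    """A single water molecule: oxygen, two hydrogens, optional dipole.

    Both O–H distances must lie in (0.5, 1.5) Å; the molecule identifier is
    stable across frames.
    """

    oxygen: np.ndarray
    hydrogen1: np.ndarray
    hydrogen2: np.ndarray
    mol_id: int
    dipole: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.oxygen = np.asarray(self.oxygen, dtype=float)
        self.hydrogen1 = np.asarray(self.hydrogen1, dtype=float)
        self.hydrogen2 = np.asarray(self.hydrogen2, dtype=float)
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=float)
        for name in ("oxygen", "hydrogen1", "hydrogen2"):
            v = getattr(self, name)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
        for h in (self.hydrogen1, self.hydrogen2):
            d = float(np.linalg.norm(h - self.oxygen))
            if not (0.5 < d < 1.5):
                raise ValueError(
                    f"O-H distance {d:.3f} Å outside (0.5, 1.5) Å for molecule "
                    f"{self.mol_id}"
                )

    @property
    def bisector(self) -> np.ndarray:
        """Unit vector from O toward the H–H midpoint (the dipole axis)."""
        v = 0.5 * (self.hydrogen1 + self.hydrogen2) - self.oxygen
        n = np.linalg.norm(v)
        if n == 0.0:
            raise ValueError("degenerate bisector")
        return v / n


@dataclass
class Frame:
    """One snapshot: ion position plus a set of water molecules in a cubic box.

    Internally array-backed; ``waters`` materializes :class:`WaterMolecule`
    views on demand.
    """

    time: float
    ion: np.ndarray
    box: float
    o_pos: np.ndarray  # (N, 3)
    h_pos: np.ndarray  # (N, 2, 3)
    mol_ids: np.ndarray  # (N,)
    dipoles: np.ndarray | None = None  # (N, 3)
    validate: bool = True

    def __post_init__(self) -> None:
        self.ion = np.asarray(self.ion, dtype=float)
        self.o_pos = np.asarray(self.o_pos, dtype=float)
        self.h_pos = np.asarray(self.h_pos, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        if not self.validate:
            return
        if not (self.box > 0):
            raise ValueError("box edge must be positive")
        n = self.o_pos.shape[0]
        if self.h_pos.shape != (n, 2, 3) or self.mol_ids.shape != (n,):
            raise ValueError("inconsistent water array shapes")
        if len(set(self.mol_ids.tolist())) != n:
            raise ValueError("molecule identifiers must be unique within a frame")
        for arr in (self.ion, self.o_pos, self.h_pos):
            if not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")
        oh = np.linalg.norm(self.h_pos - self.o_pos[:, None, :], axis=-1)
        if oh.size and not np.all((oh > 0.5) & (oh < 1.5)):
            raise ValueError("O-H distances must lie in (0.5, 1.5) Å")

    @classmethod
    def from_waters(
        cls,
        time: float,
        ion: np.ndarray,
        waters: Sequence[WaterMolecule],
        box: float,
    ) -> "Frame":
        o = np.array([w.oxygen for w in waters]).reshape(len(waters), 3)
        h = np.array([[w.hydrogen1, w.hydrogen2] for w in waters]).reshape(
            len(waters), 2, 3
        )
        ids = np.array([w.mol_id for w in waters], dtype=int)
        dip = None
        if waters and all(w.dipole is not None for w in waters):
            dip = np.array([w.dipole for w in waters])
        return cls(time, np.asarray(ion, float), box, o, h, ids, dip)

    @property
    def n_waters(self) -> int:
        return self.o_pos.shape[0]

    @property
    def waters(self) -> list[WaterMolecule]:
        out = []
        for i in range(self.n_waters):
            out.append(
                WaterMolecule(
                    self.o_pos[i],
                    self.h_pos[i, 0],
                    self.h_pos[i, 1],
                    int(self.mol_ids[i]),
                    None if self.dipoles is None else self.dipoles[i],
                )
            )
        return out


class Trajectory:
    """An ordered sequence of frames at constant sampling interval.

    Coordinates are stored unwrapped (dynamics need continuous paths); all
    distance computations in the analysis modules apply the minimum-image
    convention on demand.

    Attributes
    ----------
    times : (F,) array of time stamps in ps, strictly increasing with
        constant spacing ``dt``.
    ion_pos : (F, 3) ion coordinates.
    o_pos, h_pos : (F, N, 3) and (F, N, 2, 3) water coordinates.
    dipoles : (F, N, 3) per-molecule dipole vectors, or None.
    mol_ids : (N,) persistent molecule identifiers.
    """

    def __init__(
        self,
        times: np.ndarray,
        ion_pos: np.ndarray,
        o_pos: np.ndarray,
        h_pos: np.ndarray,
        mol_ids: np.ndarray,
        box: float,
        dipoles: np.ndarray | None = None,
        ion_label: str = "M",
        temperature: float = 300.0,
        validate: bool = True,
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.ion_pos = np.asarray(ion_pos, dtype=float)
        self.o_pos = np.asarray(o_pos, dtype=float)
        self.h_pos = np.asarray(h_pos, dtype=float)
        self.mol_ids = np.asarray(mol_ids, dtype=int)
        self.dipoles = None if dipoles is None else np.asarray(dipoles, dtype=float)
        self.box = float(box)
        self.ion_label = ion_label
        self.temperature = float(temperature)
        if validate:
            self._validate()

    def _validate(self) -> None:
        f = self.n_frames
        if f == 0:
            raise ValueError("trajectory must contain at least one frame")
        if not (self.box > 0):
            raise ValueError("box edge must be positive")
        n = self.n_waters
        if self.ion_pos.shape != (f, 3) or self.o_pos.shape != (f, n, 3):
            raise ValueError("inconsistent coordinate array shapes")
        if self.h_pos.shape != (f, n, 2, 3):
            raise ValueError("inconsistent hydrogen array shape")
        if len(set(self.mol_ids.tolist())) != n:
            raise ValueError("molecule identifiers must form a set")
        if f > 1:
            diffs = np.diff(self.times)
            if np.any(diffs <= 0):
                raise ValueError("time stamps must be strictly increasing")
            if np.max(np.abs(diffs - diffs[0])) > _TIME_TOL:
                raise ValueError("frame spacing must be constant")
        for arr in (self.times, self.ion_pos, self.o_pos, self.h_pos):
            if not np.all(np.isfinite(arr)):
                raise ValueError("all coordinates must be finite")

    # -- basic accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_waters(self) -> int:
        return self.o_pos.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def length(self) -> float:
        """Simulated time span in ps."""
        return float(self.times[-1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(
            float(self.times[i]),
            self.ion_pos[i],
            self.box,
            self.o_pos[i],
            self.h_pos[i],
            self.mol_ids,
            None if self.dipoles is None else self.dipoles[i],
            validate=False,
        )

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[Frame],
        dt: float | None = None,
        ion_label: str = "M",
        temperature: float = 300.0,
    ) -> "Trajectory":
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = frames[0].n_waters
        for k, fr in enumerate(frames):
            if fr.n_waters != n:
                raise ValueError(f"frame {k} has {fr.n_waters} waters, expected {n}")
            if set(fr.mol_ids.tolist()) != set(frames[0].mol_ids.tolist()):
                raise ValueError(f"frame {k} changes the molecule identifier set")
        order0 = np.argsort(frames[0].mol_ids)
        times = np.array([fr.time for fr in frames])
        ion = np.stack([fr.ion for fr in frames])
        # align water columns by molecule id so identifiers stay positional
        o = np.empty((len(frames), n, 3))
        h = np.empty((len(frames), n, 2, 3))
        has_dip = all(fr.dipoles is not None for fr in frames)
        dip = np.empty((len(frames), n, 3)) if has_dip and n else None
        ids_sorted = frames[0].mol_ids[order0]
        for k, fr in enumerate(frames):
            perm = np.argsort(fr.mol_ids)
            o[k] = fr.o_pos[perm]
            h[k] = fr.h_pos[perm]
            if dip is not None:
                dip[k] = fr.dipoles[perm]
        return cls(times, ion, o, h, ids_sorted, frames[0].box, dip,
                   ion_label, temperature)

    # -- geometry helpers used across analysis modules -------------------

    def oxygen_distances(self) -> np.ndarray:
        """Minimum-image ion–oxygen distances, shape (F, N)."""
        d = minimum_image(self.o_pos - self.ion_pos[:, None, :], self.box)
        return np.linalg.norm(d, axis=-1)

    def hydrogen_distances(self) -> np.ndarray:
        """Minimum-image ion–hydrogen distances, shape (F, N, 2)."""
        d = minimum_image(self.h_pos - self.ion_pos[:, None, None, :], self.box)
        return np.linalg.norm(d, axis=-1)


@dataclass
class EnergyBreakdown:
    """Cluster energy together with its isolated-fragment energies (kcal/mol)."""

    cluster_energy: float
    fragment_energies: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.fragment_energies) < 2:
            raise ValueError("an energy breakdown needs at least two fragments")


def interaction_energy(e: EnergyBreakdown) -> float:
    """Interaction energy of a hydrated cluster.

    Defined as the cluster energy minus the sum of the isolated-fragment
    energies at their minimum-energy geometries; invariant under permutation
    of the fragment list.
    """
    return float(e.cluster_energy - sum(e.fragment_energies))


@dataclass
class SpectrumK:
    """A χ(k) spectrum on a strictly increasing k-grid (Å⁻¹).

    ``k_weight`` records the exponent n of any kⁿ weighting already applied,
    so double weighting can be rejected.
    """

    k: np.ndarray
    chi: np.ndarray
    k_weight: int = 0

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        if self.k.ndim != 1 or self.k.shape != self.chi.shape:
            raise ValueError("k and chi must be 1-D arrays of equal length")
        if self.k.size and np.any(np.diff(self.k) <= 0):
            raise ValueError("k-grid must be strictly increasing")
        if self.k.size and self.k[0] < 0:
            raise ValueError("k must be non-negative")
        if self.k_weight < 0:
            raise ValueError("k-weight exponent must be >= 0")

    def copy(self) -> "SpectrumK":
        return SpectrumK(self.k.copy(), self.chi.copy(), self.k_weight)
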