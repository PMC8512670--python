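"""Shared fixtures: preset trajectories at recovery scale and micro-builders."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hydrashell.core import Frame, Trajectory, WaterMolecule
from hydrashell.synth import gen_shell_trajectory, preset

D_OH = 0.9572
HALF = math.radians(104.52 / 2.0)


def water_at(o, direction, hh_dir, mol_id):
    """A water with its bisector along ``direction`` and H-H axis ``hh_dir``."""
    o = np.asarray(o, float)
    b = np.asarray(direction, float)
    b = b / np.linalg.norm(b)
    h = np.asarray(hh_dir, float)
    h = h - (h @ b) * b
    h = h / np.linalg.norm(h)
    h1 = o + D_OH * (math.cos(HALF) * b + math.sin(HALF) * h)
    h2 = o + D_OH * (math.cos(HALF) * b - math.sin(HALF) * h)
    return WaterMolecule(o, h1, h2, mol_id)


def symmetric_water_at(o, axis, mol_id):
    """A water whose molecular centre of mass coincides with its oxygen
    (hydrogens placed antipodally); useful for hand center-of-mass oracles.
    """
    o = np.asarray(o, float)
    d = np.asarray(axis, float)
    d = d / np.linalg.norm(d) * D_OH
    return WaterMolecule(o, o + d, o - d, mol_id)


def traj_from_o_positions(o_per_frame, box=20.0, dt=0.1, ion=None,
                          symmetric=False):
    """Trajectory with waters at explicit oxygen positions per frame.

    ``o_per_frame``: (F, N, 3).  Bisectors point radially away from the ion
    (ideal ion-dipole orientation) unless ``symmetric`` is set.
    """
    o_per_frame = np.asarray(o_per_frame, float)
    frames = []
    for f in range(o_per_frame.shape[0]):
        ion_pos = np.zeros(3) if ion is None else np.asarray(ion, float)
        waters = []
        for j, o in enumerate(o_per_frame[f]):
            if symmetric:
                waters.append(symmetric_water_at(o, [0.0, 0.0, 1.0], j))
            else:
                away = o - ion_pos
                n = np.linalg.norm(away)
                away = away / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
                perp = np.cross(away, [0.12, 0.74, 0.66])
                waters.append(water_at(o, away, perp, j))
        frames.append(Frame.from_waters(f * dt, ion_pos, waters, box))
    return Trajectory.from_frames(frames)


def cube_shell_positions(radius=2.57):
    """Eight oxygens at the corners of a cube (centrosymmetric shell)."""
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                        for sz in (-1, 1)], float)
    return corners / math.sqrt(3.0) * radius


@pytest.fixture(scope="session")
def sr_traj():
    """Sr preset trajectory at recovery scale (structural targets)."""
    traj, gt = gen_shell_trajectory(preset("Sr2+", n_frames=10_000, seed=1))
    return traj, gt


@pytest.fixture(scope="session")
def ra_traj():
    """Ra preset trajectory at recovery scale (DW + histogram targets)."""
    traj, gt = gen_shell_trajectory(preset("Ra2+", n_frames=10_000, seed=3))
    return traj, gt
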