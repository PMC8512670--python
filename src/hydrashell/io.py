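"""Trajectory and spectrum file I/O.

Trajectories travel as concatenated (extended-)XYZ frames.  The comment line
of each frame carries ``time=<ps> box=<Å>``; atoms are one ion (identified by
its element label) plus water molecules as consecutive O,H,H triples in file
order.  Grouping is positional by design — no bond guessing — so parsing is
deterministic.

Spectra are plain two-column ASCII (k, χ), ``#`` comments allowed.
"""

from __future__ import annotations

import os
import re
import numpy as np

from .core import Frame, SpectrumK, Trajectory, WaterMolecule
from .errors import ContentError, DomainError, ParseError, StructuralError

__all__ = [
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_spectrum",
    "write_spectrum",
    "write_pdb_snapshot",
]

_KV_RE = re.compile(r"(\w+)=([-+0-9.eE]+)")


def _parse_comment(comment: str) -> dict[str, float]:
    return {m.group(1): float(m.group(2)) for m in _KV_RE.finditer(comment)}


def read_xyz_trajectory(
    path: str | os.PathLike,
    ion_label: str,
    box: float | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read a concatenated (extended-)XYZ file into a :class:`Trajectory`.

    Parameters
    ----------
    path : file location
    ion_label : element symbol identifying the single ion atom per frame.
    box : cubic box edge (Å); overrides any ``box=`` comment metadata.
    dt : sampling interval (ps); used to synthesize time stamps when the
        file carries no ``time=`` metadata.

    Raises
    ------
    ParseError
        Malformed frame header or truncated frame (message names the
        1-based frame index).
    StructuralError
        Atom count varies across frames.
    ContentError
        No ion, multiple ions, or leftover atoms that do not group into
        O,H,H triples.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    frames: list[Frame] = []
    i = 0
    n_atoms_ref: int | None = None
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_idx += 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"frame {frame_idx}: bad atom-count header {lines[i]!r}"
            ) from exc
        if n_atoms_ref is None:
            n_atoms_ref = n_atoms
        elif n_atoms != n_atoms_ref:
            raise StructuralError(
                f"frame {frame_idx}: atom count {n_atoms} differs from "
                f"{n_atoms_ref} in frame 1"
            )
        if i + 1 >= len(lines):
            raise ParseError(f"frame {frame_idx}: truncated frame")
        meta = _parse_comment(lines[i + 1])
        atoms: list[tuple[str, np.ndarray]] = []
        for j in range(n_atoms):
            k = i + 2 + j
            if k >= len(lines):
                raise ParseError(f"frame {frame_idx}: truncated frame")
            parts = lines[k].split()
            if len(parts) < 4:
                raise ParseError(
                    f"frame {frame_idx}: malformed atom line {lines[k]!r}"
                )
            try:
                xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ParseError(
                    f"frame {frame_idx}: malformed atom line {lines[k]!r}"
                ) from exc
            atoms.append((parts[0], xyz))
        i += 2 + n_atoms

        ion_entries = [a for a in atoms if a[0] == ion_label]
        if len(ion_entries) != 1:
            raise ContentError(
                f"frame {frame_idx}: expected exactly one {ion_label!r} atom, "
                f"found {len(ion_entries)}"
            )
        rest = [a for a in atoms if a[0] != ion_label]
        if len(rest) % 3:
            raise ParseError(
                f"frame {frame_idx}: {len(rest)} non-ion atoms do not group "
                "into O,H,H triples"
            )
        waters = []
        for w in range(len(rest) // 3):
            o, h1, h2 = rest[3 * w : 3 * w + 3]
            if o[0] != "O" or h1[0] != "H" or h2[0] != "H":
                raise ParseError(
                    f"frame {frame_idx}: triple {w + 1} is "
                    f"({o[0]},{h1[0]},{h2[0]}), expected (O,H,H)"
                )
            waters.append(WaterMolecule(o[1], h1[1], h2[1], mol_id=w))
        frame_box = box if box is not None else meta.get("box")
        if frame_box is None:
            raise ContentError(
                f"frame {frame_idx}: no box metadata and no box argument"
            )
        t = meta.get("time")
        if t is None:
            t = (frame_idx - 1) * (dt if dt is not None else 1.0)
        frames.append(Frame.from_waters(t, ion_entries[0][1], waters, frame_box))

    if not frames:
        raise ParseError("file contains no frames")
    return Trajectory.from_frames(frames, ion_label=ion_label)


def write_xyz_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as concatenated extended-XYZ.

    The per-frame comment line records ``time=<ps> box=<Å>`` so a round trip
    through :func:`read_xyz_trajectory` is lossless to 1e-6 Å.
    """
    if traj.n_frames == 0:
        raise DomainError("nothing to write: empty trajectory")
    n_atoms = 1 + 3 * traj.n_waters
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"time={traj.times[f]:.9f} box={traj.box:.9f}\n")
            x, y, z = traj.ion_pos[f]
            fh.write(f"{traj.ion_label} {x:.8f} {y:.8f} {z:.8f}\n")
            for w in range(traj.n_waters):
                ox, oy, oz = traj.o_pos[f, w]
                fh.write(f"O {ox:.8f} {oy:.8f} {oz:.8f}\n")
                for h in range(2):
                    hx, hy, hz = traj.h_pos[f, w, h]
                    fh.write(f"H {hx:.8f} {hy:.8f} {hz:.8f}\n")


def read_spectrum(path: str | os.PathLike) -> SpectrumK:
    """Read a two-column ASCII (k, χ) spectrum; weight exponent is 0."""
    ks: list[float] = []
    chis: list[float] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ParseError(f"line {ln}: expected two columns, got {s!r}")
            try:
                ks.append(float(parts[0]))
                chis.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"line {ln}: non-numeric value in {s!r}") from exc
    k = np.array(ks)
    if k.size > 1 and np.any(np.diff(k) <= 0):
        raise ContentError("k-grid is not strictly increasing")
    try:
        return SpectrumK(k, np.array(chis), k_weight=0)
    except ValueError as exc:
        raise ContentError(str(exc)) from exc


def write_spectrum(s: SpectrumK, path: str | os.PathLike,
                   header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# k_weight={s.k_weight}\n")
        for k, chi in zip(s.k, s.chi):
            fh.write(f"{k:.9g} {chi:.12g}\n")


def write_pdb_snapshot(frame: Frame, path: str | os.PathLike,
                       ion_label: str = "M") -> None:
    """Export one snapshot as a minimal PDB file for cluster inspection."""
    label = (ion_label or "M")[:2].upper()
    with open(path, "w") as fh:
        fh.write(f"CRYST1{frame.box:9.3f}{frame.box:9.3f}{frame.box:9.3f}"
                 f"  90.00  90.00  90.00 P 1           1\n")
        serial = 1

        def atom_line(name: str, element: str, resname: str, resseq: int,
                      pos: np.ndarray) -> str:
            return (
                f"ATOM  {serial:5d} {name:<4s}{resname:<4s}A{resseq:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"          {element:>2s}\n"
            )

        fh.write(atom_line(label, label, "ION", 1, frame.ion))
        serial += 1
        for w in range(frame.n_waters):
            resseq = w + 2
            fh.write(atom_line("O", "O", "HOH", resseq, frame.o_pos[w]))
            serial += 1
            for h in range(2):
                fh.write(atom_line(f"H{h + 1}", "H", "HOH", resseq,
                                   frame.h_pos[w, h]))
                serial += 1
        fh.write("END\n")
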