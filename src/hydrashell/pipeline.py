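"""Config-driven orchestration: trajectory → hydration report + artifacts.

`run_analysis` reproduces the full table of hydration-shell properties
(structural and dynamical) from a trajectory — synthetic via a preset, or
read from an extended-XYZ file — resolving shell cutoffs automatically from
the RDF minima when asked, and optionally building the snapshot-averaged
EXAFS spectrum.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import dynamics, structure
from .core import Trajectory
from .errors import HydraShellError, NoMinimumError
from .io import read_xyz_trajectory, write_spectrum, write_xyz_trajectory
from .synth import SyntheticParams, gen_shell_trajectory, preset

logger = logging.getLogger("hydrashell")

__all__ = ["RunConfig", "HydrationReport", "run_analysis"]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``preset_name`` / ``trajectory_path`` / ``params`` must
    be set.  ``cutoffs="auto"`` resolves the first/second shell boundaries
    from the M–O RDF minima.
    """

    preset_name: str | None = None
    trajectory_path: str | None = None
    params: SyntheticParams | None = None
    preset_overrides: dict[str, Any] = field(default_factory=dict)
    ion_label: str = "M"
    box: float | None = None
    dt: float | None = None
    n_frames: int = 10_000
    seed: int = 0
    cutoffs: str | tuple[float, float] = "auto"
    t_star: tuple[float, ...] = (0.0, 2.0)
    dr: float = 0.02
    reorientation: bool = False
    reorientation_window: tuple[float, float] = (2.0, 20.0)
    diffusion_window: tuple[float, float] | None = None
    exafs: dict[str, Any] | None = None   # {"stride", "k_range", "k_weight"}
    outdir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.t_star):
            raise ValueError("t* values must be non-negative")
        sources = sum(x is not None for x in
                      (self.preset_name, self.trajectory_path, self.params))
        if sources != 1:
            raise ValueError(
                "exactly one of preset_name, trajectory_path or params "
                "must be given"
            )
        if self.exafs is not None and self.exafs.get("stride", 1) < 1:
            raise ValueError("snapshot stride must be >= 1")


@dataclass
class HydrationReport:
    """All derived quantities, each with value, uncertainty, units, method."""

    ion: str = ""
    fields: dict[str, dict] = field(default_factory=dict)

    def put(self, name: str, value, sd=None, units: str = "",
            method: str = "") -> None:
        entry = {"value": value, "units": units, "method": method}
        if sd is not None:
            entry["sd"] = sd
        self.fields[name] = entry

    def value(self, name: str):
        return self.fields[name]["value"]

    def to_json(self, path=None) -> str:
        doc = {"ion": self.ion, "fields": self.fields}
        text = json.dumps(doc, indent=1, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _resolve_trajectory(cfg: RunConfig) -> tuple[Trajectory, SyntheticParams | None]:
    if cfg.trajectory_path is not None:
        traj = read_xyz_trajectory(cfg.trajectory_path, cfg.ion_label,
                                   box=cfg.box, dt=cfg.dt)
        return traj, None
    if cfg.preset_name is not None:
        p = preset(cfg.preset_name, n_frames=cfg.n_frames, seed=cfg.seed,
                   **cfg.preset_overrides)
    else:
        p = cfg.params
    traj, _gt = gen_shell_trajectory(p)
    return traj, p


def run_analysis(cfg: RunConfig) -> HydrationReport:
    """Run the full structural + dynamical analysis described by ``cfg``.

    Writes report JSON, RDF/MSD CSV profiles and optional spectra under
    ``cfg.outdir`` (if set) and returns the in-memory report.  Stage
    failures are logged with the stage name; partial artifacts are kept.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.outdir) if cfg.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    traj, params = _resolve_trajectory(cfg)
    rep = HydrationReport(ion=traj.ion_label)
    rep.put("n_frames", traj.n_frames, units="frames", method="input")
    rep.put("dt", traj.dt, units="ps", method="input")

    # ---- RDFs and cutoffs -------------------------------------------
    rdf_o = structure.compute_rdf(traj, "M-O", cfg.dr)
    rdf_h = structure.compute_rdf(traj, "M-H", cfg.dr)
    if out:
        rdf_o.to_dataframe().to_csv(out / "rdf_MO.csv", index=False)
        rdf_h.to_dataframe().to_csv(out / "rdf_MH.csv", index=False)

    peak1 = float(rdf_o.r[int(np.argmax(rdf_o.g))])
    if cfg.cutoffs == "auto":
        r1_cut = structure.find_first_minimum(rdf_o)
        try:
            sel = (rdf_o.r > r1_cut)
            peak2 = float(rdf_o.r[sel][int(np.argmax(rdf_o.g[sel]))])
            r2_cut = structure.find_first_minimum(
                rdf_o, window=(peak2, min(peak2 + 1.5, rdf_o.r[-1])))
        except NoMinimumError:
            r2_cut = min(r1_cut + 2.6, float(rdf_o.r[-1]))
            logger.warning("no second RDF minimum; fallback r2_cut=%.2f", r2_cut)
        logger.info("auto cutoffs: r1=%.2f Å, r2=%.2f Å", r1_cut, r2_cut)
    else:
        r1_cut, r2_cut = cfg.cutoffs
    rep.put("r_cut_I", r1_cut, units="Å", method="M-O RDF first minimum"
            if cfg.cutoffs == "auto" else "user")
    rep.put("r_cut_II", r2_cut, units="Å", method="M-O RDF second minimum"
            if cfg.cutoffs == "auto" else "user")

    # ---- structural block -------------------------------------------
    rep.put("R_MO_I", peak1, units="Å", method=f"M-O RDF argmax, dr={cfg.dr}")
    sel2 = (rdf_o.r > r1_cut) & (rdf_o.r <= r2_cut)
    if sel2.any():
        rep.put("R_MO_II", float(rdf_o.r[sel2][int(np.argmax(rdf_o.g[sel2]))]),
                units="Å", method="M-O RDF argmax between cutoffs")
    rep.put("CN_I", structure.coordination_number(rdf_o, r1_cut),
            units="molecules", method="n(r) at first minimum")
    rep.put("CN_II", structure.coordination_number(rdf_o, r2_cut)
            - structure.coordination_number(rdf_o, r1_cut),
            units="molecules", method="n(r2)-n(r1)")
    hist = structure.cn_histogram(traj, r1_cut)
    rep.put("CN_histogram", {str(k): v for k, v in sorted(hist.fractions.items())},
            method=f"instantaneous CN, r_cut={r1_cut:.2f}")
    rep.put("CN_mean", hist.mean, units="molecules", method="frame average")
    rep.put("DW", structure.second_cumulant(traj, r1_cut), units="Å²",
            method="pooled first-shell distance variance")
    tilt1 = structure.tilt_angles(traj, r1_cut)
    rep.put("tilt_I", tilt1.mean, sd=tilt1.sd, units="deg",
            method="bisector vs O-ion, pooled")
    tilt2 = structure.tilt_angles(traj, r2_cut, r_lo=r1_cut)
    rep.put("tilt_II", tilt2.mean, sd=tilt2.sd, units="deg",
            method="bisector vs O-ion, pooled")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ecc = structure.eccentricity(traj, r1_cut)
    rep.put("eccentricity", ecc.mean, sd=ecc.sd, units="Å",
            method="ion to shell COM, full masses")
    try:
        sel_h = rdf_h.r < r1_cut + 1.0  # first-shell H band
        mh_peak = float(rdf_h.r[sel_h][int(np.argmax(rdf_h.g[sel_h]))])
        mh_min = structure.find_first_minimum(
            rdf_h, window=(mh_peak + 0.2, min(mh_peak + 1.8, rdf_h.r[-1])))
        rep.put("R_MH_min", mh_min, units="Å", method="M-H RDF first minimum")
    except HydraShellError as exc:
        logger.warning("stage M-H minimum failed: %s", exc)
    if traj.dipoles is not None:
        try:
            dmu = structure.induced_dipole(traj, (r1_cut, r2_cut))
            for shell_name, v in dmu.dmu.items():
                rep.put(f"dmu_{shell_name}", v, sd=dmu.sd[shell_name],
                        units="D", method="shell mean |mu| - bulk mean |mu|")
        except HydraShellError as exc:
            logger.warning("stage induced dipole failed: %s", exc)

    # ---- dynamics block ---------------------------------------------
    for ts in cfg.t_star:
        try:
            res = dynamics.mean_residence_time(traj, r1_cut, ts)
            rep.put(f"MRT_tstar_{ts:g}", res.mrt, sd=res.uncertainty,
                    units="ps",
                    method=f"direct method, events={res.n_events}"
                           + (", censored" if res.censored else ""))
        except HydraShellError as exc:
            logger.warning("stage MRT(t*=%g) failed: %s", ts, exc)
    life = dynamics.cn_lifetimes(traj, r1_cut)
    rep.put("cn_lifetimes", {str(k): v for k, v in sorted(life.mean.items())},
            units="ps", method="mean constant-CN episode length")
    try:
        dwin = cfg.diffusion_window
        if dwin is None:
            hi = min(100.0, traj.length / 2.0)
            dwin = (min(10.0, hi / 4.0), hi)
        diff = dynamics.diffusion_coefficient(traj, dwin)
        rep.put("D", diff.d, sd=diff.d_err, units="1e-5 cm^2/s",
                method=f"Einstein MSD slope, window {dwin} ps")
        if out:
            import pandas as pd

            pd.DataFrame({"t": diff.lags, "msd": diff.msd}).to_csv(
                out / "msd.csv", index=False)
    except HydraShellError as exc:
        logger.warning("stage diffusion failed: %s", exc)
    if cfg.reorientation:
        for order in (1, 2):
            try:
                ror = dynamics.reorientation_time(
                    traj, "dipole", order, cfg.reorientation_window,
                    r_cut=r1_cut)
                rep.put(f"tau_{order}_mu", ror.tau, units="ps",
                        method=f"log-linear fit {cfg.reorientation_window} ps")
            except HydraShellError as exc:
                logger.warning("stage reorientation (i=%d) failed: %s",
                               order, exc)

    # ---- optional EXAFS block ---------------------------------------
    if cfg.exafs is not None:
        try:
            from . import exafs as xs

            model = cfg.exafs.get("model") or xs.parametric_path_model()
            stride = int(cfg.exafs.get("stride", max(traj.n_frames // 250, 1)))
            kw = int(cfg.exafs.get("k_weight", 2))
            k_range = tuple(cfg.exafs.get("k_range", (2.0, 10.0)))
            specs = [xs.chi_path_sum(traj.frame(i), model, r_cut=r1_cut)
                     for i in range(0, traj.n_frames, stride)]
            avg = xs.average_spectra(specs)
            weighted = xs.k_weight(avg, kw)
            ft = xs.fourier_transform_chi(weighted, k_range)
            rep.put("exafs_snapshots", avg.n_snapshots, method="stride average")
            rep.put("exafs_ft_peak", ft.peak_r, units="Å",
                    method=f"|FT| max, k range {k_range}, Hann, k^{kw}")
            if out:
                write_spectrum(weighted, out / "chi_k.dat",
                               header=f"k^{kw}-weighted snapshot average")
                np.savetxt(out / "chi_r.csv",
                           np.column_stack([ft.r, ft.magnitude]),
                           delimiter=",", header="R,magnitude")
        except HydraShellError as exc:
            logger.warning("stage EXAFS failed: %s", exc)

    if params is not None:
        rep.put("generator", {k: v for k, v in dataclasses.asdict(params).items()
                              if not isinstance(v, dict)},
                method="synthetic ground truth")
    if out:
        rep.to_json(out / "report.json")
        if cfg.trajectory_path is None and cfg.exafs is None and traj.n_frames <= 2000:
            write_xyz_trajectory(traj, out / "trajectory.xyz")
    return rep
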