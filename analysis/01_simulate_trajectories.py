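#!/usr/bin/env python
"""Generate the synthetic Sr²⁺/Ba²⁺/Ra²⁺ solution trajectories.

Each cation preset encodes the published hydration-shell structure and
dynamics; this driver realizes one trajectory per cation, records the
generator ground truth under results/, and parks the (large) extended-XYZ
files under scratch/ for the downstream steps that prefer files over
in-memory regeneration.
"""

import json
from pathlib import Path

from hydrashell.io import write_xyz_trajectory
from hydrashell.synth import PRESETS, gen_shell_trajectory, preset

N_FRAMES = 10_000
SEED = 1

results = Path(__file__).resolve().parents[1] / "results"
scratch = Path(__file__).resolve().parents[1] / "scratch" / "trajectories"
results.mkdir(exist_ok=True)
scratch.mkdir(parents=True, exist_ok=True)

summary = {}
for name in PRESETS:
    p = preset(name, n_frames=N_FRAMES, seed=SEED)
    traj, gt = gen_shell_trajectory(p)
    xyz = scratch / f"{p.ion_label}.xyz"
    write_xyz_trajectory(traj, xyz)
    gt.to_json(results / f"ground_truth_{p.ion_label}.json")
    n_exch = sum(1 for e in gt.events if e["kind"] == "leave")
    summary[name] = {"frames": traj.n_frames, "waters": traj.n_waters,
                     "span_ps": traj.length, "exchange_events": n_exch,
                     "xyz": str(xyz)}
    print(f"{name}: {traj.n_frames} frames, {traj.n_waters} waters, "
          f"{n_exch} exchange events over {traj.length:.0f} ps")

(results / "trajectories.json").write_text(json.dumps(summary, indent=1))
print(f"ground truth and summary under {results}")
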