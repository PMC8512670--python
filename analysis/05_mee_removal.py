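#!/usr/bin/env python
"""Multielectron-excitation removal: injection–recovery demonstration.

Builds a Ba-like EXAFS signal, injects a Gaussian MEE anomaly at
5.5 Å⁻¹ (the Ba L₃ position; 6.5 Å⁻¹ for Sr is run as a variant), removes
it with the spline + peak/step fit over the 5–7 Å⁻¹ search region, and
reports how well the clean signal is recovered.  Writes
results/mee_demo.json and the cleaned spectra.
"""

import json
from pathlib import Path

import numpy as np

from hydrashell import exafs
from hydrashell.io import write_spectrum
from hydrashell.synth import gen_exafs_signal

results = Path(__file__).resolve().parents[1] / "results"
results.mkdir(exist_ok=True)

model = exafs.parametric_path_model()
paths = [exafs.ScatteringPath(9, 2.81, 0.034)]

report = {}
for label, center in (("Ba", 5.5), ("Sr", 6.5)):
    amp = 0.01
    sig = gen_exafs_signal(paths, model, noise_sd=0.0,
                           mee={"center": center, "width": 0.15,
                                "amplitude": amp}, seed=11)
    clean, desc = exafs.mee_remove(sig.spectrum, region=(5.0, 7.0))
    rms = float(np.sqrt(np.mean((clean.chi - sig.clean.chi) ** 2)))
    report[label] = {"injected_center": center, "fitted": desc,
                     "rms_vs_clean": rms, "rms_over_amplitude": rms / amp}
    write_spectrum(clean, results / f"mee_cleaned_{label}.chi",
                   header=f"MEE removed (injected at {center} A^-1)")
    print(f"{label}: injected at {center}, fitted centre "
          f"{desc['center']:.2f}, residual RMS = {100 * rms / amp:.0f}% "
          "of the anomaly amplitude")

(results / "mee_demo.json").write_text(json.dumps(report, indent=1))
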