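"""Run-directory output: config echo, waveforms, summary, log."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd


def write_run(outdir, config, summary, arts):
    p = pathlib.Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    config.to_yaml(str(p / "config_echo.yaml"))

    cols = {"t": arts.t}
    cols.update({k: v for k, v in arts.inlet.items()})
    for z, zr in arts.zones.items():
        for suf, v in zr.items():
            cols[f"z{z}_{suf}"] = v
    cols["y_septum_mid_cm"] = arts.septum_center
    cols["y_wall_mid_cm"] = arts.wall_center
    pd.DataFrame(cols).to_csv(p / "waveforms.csv", index=False)

    pd.DataFrame([summary.as_row()]).to_csv(p / "summary.csv", index=False)

    with open(p / "run.log", "w") as fh:
        d = arts.diagnostics
        fh.write(f"samples: {len(arts.t)}\n")
        fh.write(f"mass drift (relative): "
                 f"{(d['mass'][-1] - d['mass'][0]) / d['mass'][0]:.3e}\n")
        fh.write(f"max lattice velocity: {np.max(d['max_v']):.4f}\n")
        fh.write(f"max no-slip residual: {np.max(d['noslip']):.3e}\n")
        fh.write(f"cycle residuals: {[f'{r:.4f}' for r in arts.cycle_residuals]}\n")
        fh.write(f"converged: {summary.converged}\n")
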