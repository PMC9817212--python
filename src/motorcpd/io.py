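"""Dataset persistence: one CSV per path plus a JSON manifest.

A simulated dataset directory contains ``path_0000.csv`` ... (columns frame,
t, x_obs) and ``manifest.json`` holding the scenario settings, the master
seed, and the per-path ground truth (k, change times, segment velocities).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ScenarioSpec, SimulatedPath

__all__ = ["write_dataset", "read_dataset_manifest", "read_path_csv"]


def write_dataset(
    paths: list[SimulatedPath],
    spec: ScenarioSpec,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = []
    for i, p in enumerate(paths):
        pd.DataFrame(
            {
                "frame": np.arange(p.obs_times.size),
                "t": p.obs_times,
                "x_obs": p.obs_positions,
            }
        ).to_csv(out / f"path_{i:04d}.csv", index=False)
        truth.append(
            {
                "k": p.true_k,
                "change_times": list(p.schedule.change_times),
                "velocities": [float(v) for v in p.true_velocities],
            }
        )
    manifest = {
        "scenario": {
            "case_id": spec.case_id,
            "spacing": spec.spacing,
            "v_slow": list(spec.v_slow),
            "v_fast": list(spec.v_fast),
            "change_rate": spec.change_rate,
            "n_paths": spec.n_paths,
            "first_segment_fast": spec.first_segment_fast,
        },
        "physical": {
            "step_size": spec.params.step_size,
            "kappa_over_gamma": spec.params.kappa_over_gamma,
            "diffusivity": spec.params.diffusivity,
            "obs_noise_sd": spec.params.obs_noise_sd,
            "sim_dt": spec.params.sim_dt,
            "frame_dt": spec.params.frame_dt,
            "duration": spec.params.duration,
        },
        "seed": seed,
        "truth": truth,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset_manifest(dataset_dir: str | Path) -> dict:
    return json.loads((Path(dataset_dir) / "manifest.json").read_text())


def read_path_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """(times, positions) of one stored path."""
    df = pd.read_csv(path)
    return df["t"].to_numpy(), df["x_obs"].to_numpy()
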