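"""Plain-text interchange formats.

Raw trial files are tab-separated with a commented header and two row kinds::

    # vrgaze raw trial v1
    # participant=P00 scene=S001 phase=encoding
    EYE   t  ex  ey  ez          (eye-in-head unit vector at t ms)
    HEAD  t  qw  qx  qy  qz      (head orientation quaternion at t ms)

Study configs round-trip through YAML; trial metadata, gaze series and
fixation tables are tab-separated with a header row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .synth import RawTrial, StudyConfig

__all__ = [
    "write_raw_trial",
    "read_raw_trial",
    "write_config",
    "read_config",
    "write_trial_table",
    "read_trial_table",
]


def write_raw_trial(trial: RawTrial, path):
    with open(path, "w") as fh:
        fh.write("# vrgaze raw trial v1\n")
        fh.write(f"# participant={trial.participant_id} "
                 f"scene={trial.scene_id} phase={trial.phase}\n")
        for t, v in zip(trial.eye_t, trial.eye_vec):
            fh.write(f"EYE\t{t:.6f}\t{v[0]:.12f}\t{v[1]:.12f}\t{v[2]:.12f}\n")
        for t, q in zip(trial.head_t, trial.head_q):
            fh.write(f"HEAD\t{t:.6f}\t{q[0]:.12f}\t{q[1]:.12f}\t{q[2]:.12f}"
                     f"\t{q[3]:.12f}\n")


def read_raw_trial(path) -> RawTrial:
    """Read a raw-trial file; ground-truth fields are empty (real recordings
    carry no generator truth)."""
    meta = {}
    eye_rows, head_rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            parts = line.split("\t")
            if parts[0] == "EYE":
                eye_rows.append([float(x) for x in parts[1:5]])
            elif parts[0] == "HEAD":
                head_rows.append([float(x) for x in parts[1:6]])
            else:
                raise ValueError(f"unknown row kind: {parts[0]!r}")
    eye = np.asarray(eye_rows, dtype=float)
    head = np.asarray(head_rows, dtype=float)
    if eye.size == 0 or head.size == 0:
        raise ValueError("raw trial file must contain EYE and HEAD rows")
    empty = np.empty(0)
    return RawTrial(
        participant_id=meta.get("participant", "?"),
        scene_id=meta.get("scene", "?"),
        phase=meta.get("phase", "encoding"),
        eye_t=eye[:, 0], eye_vec=eye[:, 1:4],
        head_t=head[:, 0], head_q=head[:, 1:5],
        gt_lon=empty, gt_lat=empty, gt_on=empty, gt_off=empty,
    )


def write_config(config: StudyConfig, path):
    from dataclasses import asdict

    d = asdict(config)
    d["mover_scale_range"] = list(d["mover_scale_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_config(path) -> StudyConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "mover_scale_range" in d:
        d["mover_scale_range"] = tuple(d["mover_scale_range"])
    return StudyConfig(**d)


def write_trial_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
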