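"""Trajectory, feature and configuration file I/O.

Trajectories are written either as multi-frame XYZ-style text (20 records
per frame, ``<strand>:<base-index>:<base>`` labels in the atom field, frame
metadata in the comment line) or as an ``.npz`` binary container.  Run
parameters use a flat ``key = value`` text format.  Units are nm and ns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import constants as C
from .duplex_synth import Trajectory

__all__ = [
    "write_xyz",
    "read_xyz",
    "save_trajectory_npz",
    "load_trajectory_npz",
    "save_features",
    "load_features",
    "write_config",
    "read_config",
]


def write_xyz(path, traj: Trajectory, bases: str = "N" * C.SEQ_LENGTH) -> None:
    """Write a trajectory as multi-frame XYZ text (coordinates in nm)."""
    if traj.frames is None:
        raise ValueError("trajectory has no coordinates")
    L = traj.frames.shape[2]
    with open(path, "w") as fh:
        for f in range(traj.frames.shape[0]):
            fh.write(f"{2 * L}\n")
            label = (
                traj.truth_labels[f] if traj.truth_labels is not None else "?"
            )
            fh.write(
                f"frame={f} t_ns={f * traj.dt_save:.6f} "
                f"dt_save={traj.dt_save} state={label}\n"
            )
            for s in range(2):
                for b in range(L):
                    x, y, z = traj.frames[f, s, b]
                    fh.write(
                        f"{s + 1}:{b}:{bases[b]} {x:.6f} {y:.6f} {z:.6f}\n"
                    )


def read_xyz(path) -> Trajectory:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz`."""
    frames = []
    labels = []
    dt_save = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n_atoms = int(lines[i])
        meta = dict(
            kv.split("=", 1) for kv in lines[i + 1].split() if "=" in kv
        )
        dt_save = float(meta.get("dt_save", dt_save or 1.0))
        labels.append(meta.get("state", "?"))
        L = n_atoms // 2
        coords = np.empty((2, L, 3), dtype=np.float32)
        for a in range(n_atoms):
            parts = lines[i + 2 + a].split()
            s, b, _ = parts[0].split(":")
            coords[int(s) - 1, int(b)] = [float(v) for v in parts[1:4]]
        frames.append(coords)
        i += 2 + n_atoms
    labels_arr = np.array(labels, dtype=object)
    if all(l == "?" for l in labels):
        labels_arr = None
    return Trajectory(
        frames=np.stack(frames), dt_save=dt_save, seed=-1,
        truth_labels=labels_arr,
    )


def save_trajectory_npz(path, traj: Trajectory) -> None:
    np.savez_compressed(
        path,
        frames=traj.frames if traj.frames is not None else np.empty(0),
        dt_save=traj.dt_save,
        seed=traj.seed,
        truth_labels=(
            np.asarray(traj.truth_labels, dtype="U4")
            if traj.truth_labels is not None else np.empty(0, dtype="U4")
        ),
    )


def load_trajectory_npz(path) -> Trajectory:
    z = np.load(path, allow_pickle=False)
    frames = z["frames"] if z["frames"].size else None
    labels = (
        z["truth_labels"].astype(object) if z["truth_labels"].size else None
    )
    return Trajectory(
        frames=frames, dt_save=float(z["dt_save"]), seed=int(z["seed"]),
        truth_labels=labels,
    )


_FEATURE_HEADER = (
    "row-major (i, j): strand-swap symmetrized reciprocal distances 1/nm, "
    "i = strand-1 base, j = strand-2 base"
)


def save_features(path, features: np.ndarray) -> None:
    np.savez_compressed(
        path, features=features, ordering=_FEATURE_HEADER
    )


def load_features(path) -> np.ndarray:
    return np.load(path)["features"]


def write_config(path, config: dict) -> None:
    """Flat ``key = value`` config file; nested keys use dots."""
    with open(path, "w") as fh:
        for k in sorted(config):
            fh.write(f"{k} = {config[k]}\n")


def _parse_value(text: str):
    text = text.strip()
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def read_config(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = _parse_value(v)
    return out
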