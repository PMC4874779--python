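"""Session and trial containers plus the on-disk session format.

A session directory contains four human-diffable text files:

* ``meta.yaml`` -- units, timestep duration, block structure, per-block BMI
  mappings, provenance;
* ``trials.csv`` -- one row per trial (id, target, block, outcome, events);
* ``timesteps.csv`` -- per-timestep cursor kinematics (trial_id, t, p, v);
* ``spikes.csv`` -- per-timestep raw spike counts, one column per unit.

Smoothed counts are not stored; they are recomputed from the raw counts and
the block mapping's smoothing window on load.  Round-trips are lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .bmi import BMIMapping, mapping_from_dict, _mapping_dict, smooth_count_matrix, decode_velocity

__all__ = ["Trial", "Session", "SessionFormatError", "write_session", "read_session"]


class SessionFormatError(ValueError):
    """A session file violates the format or a stored-trial invariant."""


@dataclass
class Trial:
    """One center-out BMI trial.

    ``target_onset`` and ``acquisition`` are 0-based timestep indices into
    the per-timestep arrays; ``acquisition`` is None for failed trials.
    """

    trial_id: int
    target: np.ndarray            # (2,) mm
    block: str
    success: bool
    target_onset: int
    acquisition: Optional[int]
    pos: np.ndarray               # (T, 2) mm
    vel: np.ndarray               # (T, 2) mm/s
    spikes_raw: np.ndarray        # (T, q) counts
    spikes_smooth: Optional[np.ndarray] = None  # (T, q), derived

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float).reshape(2)
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        self.spikes_raw = np.asarray(self.spikes_raw)
        if not (len(self.pos) == len(self.vel) == len(self.spikes_raw)):
            raise SessionFormatError(
                f"trial {self.trial_id}: per-timestep arrays have unequal lengths"
            )

    @property
    def n_timesteps(self) -> int:
        return len(self.pos)

    @property
    def n_units(self) -> int:
        return self.spikes_raw.shape[1]

    @property
    def end(self) -> int:
        """Last analyzed timestep: acquisition if successful, else the final one."""
        return self.acquisition if self.acquisition is not None else self.n_timesteps - 1


@dataclass
class Session:
    """An ordered collection of trials sharing a unit population.

    ``mappings`` gives the decoder in effect per block label; block labels
    partition the trial list contiguously.
    """

    dt: float
    unit_labels: List[str]
    mappings: Dict[str, BMIMapping]
    trials: List[Trial]
    provenance: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.unit_labels)

    @property
    def blocks(self) -> List[str]:
        out: List[str] = []
        for tr in self.trials:
            if not out or out[-1] != tr.block:
                out.append(tr.block)
        return out

    def mapping_for(self, trial: Trial) -> BMIMapping:
        return self.mappings[trial.block]

    def trials_in_block(self, block: str) -> List[Trial]:
        return [tr for tr in self.trials if tr.block == block]

    def validate(self, atol: float = 1e-6) -> float:
        """Check stored-trial invariants; returns the max kinematic deviation.

        Verifies that block labels partition the trial list contiguously,
        spike counts are nonnegative, positions integrate velocities
        (p_t = p_{t-1} + v_{t-1} dt) and velocities equal the block mapping's
        decode of the smoothed counts.
        """
        seen = set()
        max_dev = 0.0
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if cur in seen:
                raise SessionFormatError(f"block {cur!r} is not contiguous")
            seen.add(prev)
        for tr in self.trials:
            if tr.n_units != self.n_units:
                raise SessionFormatError(f"trial {tr.trial_id}: unit count mismatch")
            if np.any(np.asarray(tr.spikes_raw, dtype=float) < 0):
                raise SessionFormatError(f"trial {tr.trial_id}: negative spike count")
            m = self.mapping_for(tr)
            if tr.n_timesteps > 1:
                pred = tr.pos[:-1] + tr.vel[:-1] * self.dt
                max_dev = max(max_dev, float(np.abs(pred - tr.pos[1:]).max()))
            sm = smooth_count_matrix(tr.spikes_raw, m.smooth_window)
            vdev = float(np.abs(decode_velocity(sm, m) - tr.vel).max())
            max_dev = max(max_dev, vdev)
            if max_dev > atol:
                raise SessionFormatError(
                    f"trial {tr.trial_id}: kinematics deviate from mapping by {max_dev:.3g}"
                )
        return max_dev

    def attach_smoothed(self) -> None:
        """(Re)compute smoothed counts per trial from the block mapping."""
        for tr in self.trials:
            w = self.mapping_for(tr).smooth_window
            tr.spikes_smooth = smooth_count_matrix(tr.spikes_raw, w)


def write_session(session: Session, path) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {
        "dt": session.dt,
        "unit_labels": list(session.unit_labels),
        "blocks": session.blocks,
        "mappings": {k: _mapping_dict(m) for k, m in session.mappings.items()},
        "provenance": session.provenance,
    }
    with open(os.path.join(path, "meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    trows = []
    srows, krows = [], []
    for tr in session.trials:
        trows.append(
            {
                "trial_id": tr.trial_id,
                "target_x": tr.target[0],
                "target_y": tr.target[1],
                "block": tr.block,
                "outcome": "success" if tr.success else "failure",
                "target_onset": tr.target_onset,
                "acquisition": -1 if tr.acquisition is None else tr.acquisition,
            }
        )
        for t in range(tr.n_timesteps):
            krows.append(
                {
                    "trial_id": tr.trial_id,
                    "t": t,
                    "p_x": repr(float(tr.pos[t, 0])),
                    "p_y": repr(float(tr.pos[t, 1])),
                    "v_x": repr(float(tr.vel[t, 0])),
                    "v_y": repr(float(tr.vel[t, 1])),
                }
            )
        for t in range(tr.n_timesteps):
            row = {"trial_id": tr.trial_id, "t": t}
            for j, lab in enumerate(session.unit_labels):
                row[lab] = int(tr.spikes_raw[t, j])
            srows.append(row)
    pd.DataFrame(trows).to_csv(os.path.join(path, "trials.csv"), index=False)
    pd.DataFrame(krows).to_csv(os.path.join(path, "timesteps.csv"), index=False)
    pd.DataFrame(srows).to_csv(os.path.join(path, "spikes.csv"), index=False)


def read_session(path, validate: bool = True) -> Session:
    with open(os.path.join(path, "meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    mappings = {k: mapping_from_dict(d) for k, d in meta["mappings"].items()}
    trials_df = pd.read_csv(os.path.join(path, "trials.csv"),
                            float_precision="round_trip")
    steps_df = pd.read_csv(os.path.join(path, "timesteps.csv"),
                           float_precision="round_trip")
    spikes_df = pd.read_csv(os.path.join(path, "spikes.csv"))
    unit_labels = list(meta["unit_labels"])

    for i, row in spikes_df.iterrows():
        for lab in unit_labels:
            if row[lab] < 0:
                raise SessionFormatError(
                    f"spikes.csv row {i}: negative count for unit {lab}"
                )

    trials: List[Trial] = []
    for _, row in trials_df.iterrows():
        tid = int(row["trial_id"])
        k = steps_df[steps_df.trial_id == tid].sort_values("t")
        s = spikes_df[spikes_df.trial_id == tid].sort_values("t")
        if len(k) == 0 or len(k) != len(s):
            raise SessionFormatError(f"trial {tid}: timestep/spike row mismatch")
        acq = int(row["acquisition"])
        trials.append(
            Trial(
                trial_id=tid,
                target=np.array([row["target_x"], row["target_y"]], dtype=float),
                block=str(row["block"]),
                success=row["outcome"] == "success",
                target_onset=int(row["target_onset"]),
                acquisition=None if acq < 0 else acq,
                pos=k[["p_x", "p_y"]].to_numpy(dtype=float),
                vel=k[["v_x", "v_y"]].to_numpy(dtype=float),
                spikes_raw=s[unit_labels].to_numpy(dtype=int),
            )
        )
    session = Session(
        dt=float(meta["dt"]),
        unit_labels=unit_labels,
        mappings=mappings,
        trials=trials,
        provenance=meta.get("provenance", {}) or {},
    )
    session.attach_smoothed()
    if validate:
        session.validate()
    return session
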