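"""The experimenter-side BMI mapping: decoding, smoothing, calibration, perturbation.

The decoder is a linear position/velocity mapping operating on boxcar-smoothed
spike counts.  With timestep duration ``dt`` and smoothing window ``W``
(timesteps), the cursor evolves as

    p_t = p_{t-1} + v_{t-1} * dt
    v_t = Bv @ u_t + bv,        u_t = mean of the last W raw count vectors.

``Bv`` is 2 x q (mm/s per count); each column is the "pushing vector" of one
neuronal unit -- the velocity contribution of a single (smoothed) spike.
The full state-space form x_t = A x_{t-1} + B u_t + b over x = [p; v] is
derivable from these fields (see :meth:`BMIMapping.state_space`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "BMIMapping",
    "CursorState",
    "PerturbationSpec",
    "smooth_counts",
    "decode_velocity",
    "unsmoothed_velocity",
    "step_cursor",
    "perturb_mapping",
    "pushing_vectors",
    "calibrate_mapping",
    "run_assisted_sequence",
    "fit_cosine_tuning",
    "save_mapping",
    "load_mapping",
]

DEFAULT_DT = 0.033  # s, 33-ms spike-count bins
DEFAULT_WINDOW = 5  # timesteps of boxcar smoothing (167 ms)


@dataclass(frozen=True)
class CursorState:
    """Cursor position (mm) and velocity (mm/s)."""

    p: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float).reshape(2))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float).reshape(2))
        if not (np.all(np.isfinite(self.p)) and np.all(np.isfinite(self.v))):
            raise ValueError("cursor state must be finite")

    @property
    def x(self) -> np.ndarray:
        """Concatenated state [p; v]."""
        return np.concatenate([self.p, self.v])


@dataclass
class BMIMapping:
    """Linear velocity decoder with boxcar smoothing."""

    Bv: np.ndarray  # (2, q) mm/s per smoothed count
    bv: np.ndarray  # (2,) mm/s
    dt: float = DEFAULT_DT
    smooth_window: int = DEFAULT_WINDOW
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Bv = np.asarray(self.Bv, dtype=float)
        self.bv = np.asarray(self.bv, dtype=float).reshape(2)
        if self.Bv.ndim != 2 or self.Bv.shape[0] != 2:
            raise ValueError("Bv must be a 2 x q matrix")
        if self.dt <= 0 or self.smooth_window < 1:
            raise ValueError("dt must be positive and smooth_window >= 1")

    @property
    def n_units(self) -> int:
        return self.Bv.shape[1]

    def state_space(self):
        """Full (A, B, b) over the concatenated state x = [p; v]."""
        q = self.n_units
        A = np.zeros((4, 4))
        A[:2, :2] = np.eye(2)
        A[:2, 2:] = np.eye(2) * self.dt
        B = np.vstack([np.zeros((2, q)), self.Bv])
        b = np.concatenate([np.zeros(2), self.bv])
        return A, B, b

    def copy(self) -> "BMIMapping":
        return BMIMapping(
            self.Bv.copy(), self.bv.copy(), self.dt, self.smooth_window,
            dict(self.provenance),
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """Rotation of a subset of units' decoded pushing directions.

    Either give ``rotated_units`` explicitly or a ``unit_fraction`` in (0, 1]
    from which ``round(unit_fraction * q)`` units are drawn with ``seed``.
    """

    rotation_angle: float  # degrees, CCW positive
    unit_fraction: float = 1.0
    rotated_units: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self):
        if self.rotated_units is None and not (0.0 < self.unit_fraction <= 1.0):
            raise ValueError("unit_fraction must be in (0, 1]")
        if self.rotated_units is not None:
            object.__setattr__(self, "rotated_units", tuple(int(i) for i in self.rotated_units))

    def resolve_units(self, q: int) -> np.ndarray:
        if self.rotated_units is not None:
            units = np.asarray(self.rotated_units, dtype=int)
        else:
            k = int(round(self.unit_fraction * q))
            rng = np.random.default_rng(self.seed)
            units = np.sort(rng.choice(q, size=k, replace=False))
        if units.size == 0:
            raise ValueError("perturbation selects no units")
        return units


def rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def smooth_counts(raw_history: Sequence[np.ndarray], window: int) -> np.ndarray:
    """Mean of the last ``min(window, available)`` raw count vectors.

    At trial start, with fewer than ``window`` timesteps of history, the
    running mean over available history is used (converging to the boxcar by
    timestep ``window``).
    """
    if len(raw_history) == 0:
        raise ValueError("spike-count history is empty")
    h = np.asarray(raw_history[-window:], dtype=float)
    return h.mean(axis=0)


def smooth_count_matrix(raw: np.ndarray, window: int) -> np.ndarray:
    """Causal running-boxcar smoothing of a (T, q) raw count matrix."""
    raw = np.asarray(raw, dtype=float)
    out = np.empty_like(raw)
    csum = np.cumsum(raw, axis=0)
    T = raw.shape[0]
    for t in range(T):
        lo = max(0, t - window + 1)
        s = csum[t] - (csum[lo - 1] if lo > 0 else 0.0)
        out[t] = s / (t - lo + 1)
    return out


def decode_velocity(u: np.ndarray, mapping: BMIMapping) -> np.ndarray:
    """v = Bv @ u + bv for a single smoothed count vector or a (T, q) stack."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != mapping.n_units:
        raise ValueError(
            f"count vector has {u.shape[-1]} units, mapping expects {mapping.n_units}"
        )
    return u @ mapping.Bv.T + mapping.bv


def unsmoothed_velocity(u_raw: np.ndarray, mapping: BMIMapping) -> np.ndarray:
    """Single-timestep (unsmoothed) velocity command: Bv @ u_raw + bv."""
    return decode_velocity(u_raw, mapping)


def step_cursor(state: CursorState, v_new: np.ndarray, mapping: BMIMapping) -> CursorState:
    """One cursor update: position advances with the *previous* velocity."""
    return CursorState(state.p + state.v * mapping.dt, v_new)


def pushing_vectors(mapping: BMIMapping) -> np.ndarray:
    """(q, 2) array of per-unit pushing vectors (columns of Bv)."""
    return mapping.Bv.T.copy()


def perturb_mapping(mapping: BMIMapping, spec: PerturbationSpec) -> BMIMapping:
    """Rotate the selected units' decoded pushing directions by the spec's angle.

    Pushing-vector magnitudes are preserved (pure rotation) and unselected
    columns are unchanged.  When the mapping records the baseline rates its
    offset cancels (``provenance["baseline_rates"]``), each rotated unit's
    share of that baseline cancellation rotates with its pushing vector --
    so baseline firing still decodes to zero velocity and a 100% rotation
    acts as an exact visuomotor rotation of the decoded velocities.
    """
    units = spec.resolve_units(mapping.n_units)
    R = rotation_matrix(spec.rotation_angle)
    out = mapping.copy()
    out.Bv[:, units] = R @ out.Bv[:, units]
    baseline = mapping.provenance.get("baseline_rates")
    if baseline is not None:
        delta = out.Bv - mapping.Bv
        out.bv = out.bv - delta @ np.asarray(baseline, dtype=float)
    out.provenance = dict(mapping.provenance)
    out.provenance["perturbation"] = {
        "rotation_angle": spec.rotation_angle,
        "rotated_units": [int(i) for i in units],
        "seed": spec.seed,
    }
    return out


# ---------------------------------------------------------------------------
# Closed-loop calibration (population-vector style)
# ---------------------------------------------------------------------------

def fit_cosine_tuning(rates: np.ndarray, directions_deg: np.ndarray):
    """Per-unit regression of trial-mean rates on target-direction unit vectors.

    Fits ``r_i = b0_i + m_i . [cos(theta), sin(theta)]`` by least squares.

    Returns ``(modulation, baseline)`` where ``modulation`` is (q, 2) -- each
    row the fitted modulation (preferred-direction) vector -- and ``baseline``
    is (q,).
    """
    rates = np.asarray(rates, dtype=float)
    th = np.radians(np.asarray(directions_deg, dtype=float))
    X = np.column_stack([np.cos(th), np.sin(th), np.ones_like(th)])
    if rates.shape[0] < 3 or np.linalg.matrix_rank(X) < 3:
        raise ValueError("calibration requires >= 3 trials spanning distinct directions")
    coef, *_ = np.linalg.lstsq(X, rates, rcond=None)
    modulation = coef[:2].T  # (q, 2)
    baseline = coef[2]
    return modulation, baseline


def _assemble_mapping(modulation, baseline, speed_scale, dt, window) -> BMIMapping:
    # Pushing vector of unit i is its modulation vector, scaled so decoded
    # speeds land in a useful range; bv cancels baseline firing so that
    # baseline activity decodes to zero velocity.
    Bv = speed_scale * modulation.T
    bv = -Bv @ baseline
    return BMIMapping(Bv, bv, dt=dt, smooth_window=window)


def calibrate_mapping(
    calibration_trials,
    schedule: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.0),
    target_speed: float = 100.0,
    dt: float = DEFAULT_DT,
    smooth_window: int = DEFAULT_WINDOW,
) -> BMIMapping:
    """Iterative closed-loop calibration following the population-vector recipe.

    ``calibration_trials`` is a sequence of per-sequence lists of
    ``(direction_deg, mean_rate_vector)`` pairs: one sequence of radial
    targets per schedule entry.  After each sequence the mapping is refit by
    regressing every unit's trial-mean rate on the target-direction unit
    vectors across *all* trials observed so far; the next sequence runs under
    that mapping with perpendicular-velocity attenuation per ``schedule``
    (1.0 = full assistance, 0.0 = none).  The rates themselves are supplied
    by the caller (recorded, or produced by a synthetic subject via
    :func:`run_assisted_sequence`), so this function is the regression and
    assembly step shared by both paths.

    ``target_speed`` sets the scale of the decoded velocities: the mapping is
    normalized so the mean decoded speed toward the calibration targets
    equals ``target_speed`` mm/s.
    """
    seqs = list(calibration_trials)
    if len(seqs) == 0:
        raise ValueError("no calibration sequences given")
    dirs: list = []
    rates: list = []
    mapping = None
    for seq in seqs:
        for d, r in seq:
            dirs.append(float(d))
            rates.append(np.asarray(r, dtype=float))
        modulation, baseline = fit_cosine_tuning(np.asarray(rates), np.asarray(dirs))
        # Normalize decoded speed: mean over calibration trials of the decoded
        # speed for the trial's own direction.
        raw = _assemble_mapping(modulation, baseline, 1.0, dt, smooth_window)
        v = decode_velocity(np.asarray(rates), raw)
        mean_speed = float(np.mean(np.linalg.norm(v, axis=1)))
        scale = target_speed / mean_speed if mean_speed > 0 else 1.0
        mapping = _assemble_mapping(modulation, baseline, scale, dt, smooth_window)
    mapping.provenance = {
        "calibration": {
            "n_sequences": len(seqs),
            "n_trials": len(dirs),
            "schedule": list(schedule),
            "target_speed": target_speed,
        }
    }
    return mapping


def assisted_velocity(v: np.ndarray, target_dir: np.ndarray, attenuation: float) -> np.ndarray:
    """Attenuate the velocity component perpendicular to the target direction.

    ``attenuation`` = 1 removes the perpendicular component entirely (full
    assistance); 0 leaves the velocity untouched.
    """
    u = np.asarray(target_dir, dtype=float)
    u = u / np.linalg.norm(u)
    par = np.dot(v, u) * u
    perp = v - par
    return par + (1.0 - attenuation) * perp


def run_assisted_sequence(
    mapping: Optional[BMIMapping],
    directions_deg: Sequence[float],
    rate_fn,
    attenuation: float,
    n_steps: int = 30,
    rng: Optional[np.random.Generator] = None,
):
    """Run one closed-loop calibration sequence under assistance.

    ``rate_fn(direction_deg, rng) -> (q,) counts`` supplies the subject's
    spiking for one timestep while aiming at a target in the given direction.
    Returns ``(trials, trajectories)`` where ``trials`` is a list of
    ``(direction_deg, mean_rate_vector)`` pairs and each trajectory is the
    (n_steps+1, 2) cursor path (stationary if ``mapping`` is None, as in the
    very first sequence).
    """
    rng = rng or np.random.default_rng(0)
    trials, paths = [], []
    for d in directions_deg:
        tdir = np.array([np.cos(np.radians(d)), np.sin(np.radians(d))])
        counts = []
        p = np.zeros(2)
        v = np.zeros(2)
        path = [p.copy()]
        history: list = []
        for _ in range(n_steps):
            u_raw = np.asarray(rate_fn(d, rng), dtype=float)
            counts.append(u_raw)
            if mapping is not None:
                history.append(u_raw)
                u_s = smooth_counts(history, mapping.smooth_window)
                p = p + v * mapping.dt
                v = assisted_velocity(decode_velocity(u_s, mapping), tdir, attenuation)
            path.append(p.copy())
        trials.append((d, np.mean(counts, axis=0)))
        paths.append(np.asarray(path))
    return trials, paths


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _mapping_dict(mapping: BMIMapping) -> dict:
    return {
        "Bv": mapping.Bv.tolist(),
        "bv": mapping.bv.tolist(),
        "dt": mapping.dt,
        "smooth_window": mapping.smooth_window,
        "provenance": mapping.provenance,
    }


def save_mapping(mapping: BMIMapping, path) -> None:
    """Write the mapping as a structured-text (YAML) document; exact round-trip."""
    with open(path, "w") as fh:
        yaml.safe_dump(_mapping_dict(mapping), fh, sort_keys=True)


def load_mapping(path) -> BMIMapping:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return mapping_from_dict(d)


def mapping_from_dict(d: dict) -> BMIMapping:
    return BMIMapping(
        np.asarray(d["Bv"], dtype=float),
        np.asarray(d["bv"], dtype=float),
        dt=float(d["dt"]),
        smooth_window=int(d["smooth_window"]),
        provenance=d.get("provenance", {}) or {},
    )
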