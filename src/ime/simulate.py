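"""Closed-loop synthetic-session generator.

The generator emulates a center-out BMI session in which a subject with a
*true* internal forward model steers a cursor driven by a (possibly
different) linear decoder:

1. at each timestep the subject grounds its belief at tau-delayed visual
   feedback and unrolls its internal model through the raw spike counts it
   has issued since, obtaining an up-to-date position belief;
2. it aims straight at the (sensory-delayed) target from that belief, with
   an intended speed set by a saturating distance-to-speed policy;
3. it emits the minimum-norm mean spike pattern whose image under the true
   internal model realizes the intended velocity, plus seeded variability in
   the null space of the internal model's readout;
4. rates are rectified (clipping logged) and spike counts drawn Poisson,
   optionally with cross-unit correlation through a Gaussian copula;
5. the decoder updates the actual cursor from boxcar-smoothed counts;
6. the trial ends on sustained cursor-target overlap or timeout.

Internal-model mismatch is configurable as a global rotation of the decoder
readout, per-unit gain jitter, and components in the null space of the
decoder readout; with zero mismatch the subject's model is decoder-
equivalent.  Block structure (intuitive / perturbation / washout) and
trial-by-trial drift of the subject's model toward the active decoder
support adaptation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg

from .bmi import (
    BMIMapping, PerturbationSpec, decode_velocity, perturb_mapping,
    rotation_matrix, smooth_counts,
)
from .estimator import InternalModel, decoder_equivalent_internal, unroll_velocities
from .session import Session, Trial

__all__ = [
    "SessionSpec",
    "MismatchSpec",
    "GroundTruth",
    "default_mapping",
    "make_ground_truth",
    "simulate_session",
    "simulate_perturbation_experiment",
]


@dataclass(frozen=True)
class SessionSpec:
    """Task geometry, timing and size of a synthetic session.

    Defaults follow the 2-D center-out task this package models: 16 evenly
    spaced radial targets 85 mm from the workspace center, 7-mm cursor and
    target radii, 33-ms timesteps, a 3-timestep visuomotor delay, and
    success rates near 100% under the intuitive mapping.
    """

    n_units: int = 26
    n_targets: int = 16
    center_to_target: float = 85.0   # mm
    cursor_radius: float = 7.0       # mm
    target_radius: float = 7.0       # mm
    trials_per_target: int = 10
    tau: int = 3                     # subject grounding delay, timesteps
    sensory_delay: int = 3           # target-onset reaction delay, timesteps
    dt: float = 0.033                # s
    hold_steps: Tuple[int, int] = (4, 10)   # pre-onset center hold (uniform range)
    target_hold_steps: int = 2
    timeout_steps: int = 75          # post-onset cap (~2.5 s)
    max_speed: float = 120.0         # mm/s intended-speed ceiling
    ramp_distance: float = 30.0      # mm: distance at which intended speed saturates
    push_saturation: float = 150.0   # mm/s cap on the steady-state velocity a
                                     # sustained neural push can produce
    seed: int = 0

    def target_positions(self) -> np.ndarray:
        ang = 2 * np.pi * np.arange(self.n_targets) / self.n_targets
        return self.center_to_target * np.column_stack([np.cos(ang), np.sin(ang)])

    def intended_speed(self, distance) -> np.ndarray:
        """Saturating ramp: fast when far from the aim point, slow near it."""
        return self.max_speed * np.minimum(1.0, np.asarray(distance) / self.ramp_distance)


@dataclass(frozen=True)
class MismatchSpec:
    """Structured difference between the subject's model and the decoder.

    ``rotation`` rotates every believed pushing vector by the given angle
    (degrees, CCW); ``gain_jitter`` scales each unit's vector by
    ``1 + gain_jitter * z`` with standard-normal z; ``null_scale`` adds
    components in the null space of the decoder readout with RMS magnitude
    ``null_scale`` relative to the decoder's mean pushing-vector norm.
    All zero means the subject's model is decoder-equivalent.
    """

    rotation: float = 0.0
    gain_jitter: float = 0.0
    null_scale: float = 0.0

    @property
    def is_null(self) -> bool:
        return self.rotation == 0 and self.gain_jitter == 0 and self.null_scale == 0


@dataclass
class GroundTruth:
    """Generative state of the synthetic subject."""

    true_internal: InternalModel
    decoder: BMIMapping
    baseline_rates: np.ndarray          # (q,) counts/timestep
    null_sigma: float = 0.5             # s.d. of null-space activity (counts)
    noise_corr: Optional[np.ndarray] = None  # optional (q, q) count correlation
    aim_mode: str = "internal"          # "internal" | "feedback"
    spike_noise: str = "poisson"        # "poisson" | "none" (emit mean rates)
    push_policy: str = "compensate"     # "compensate": realize v* exactly each step;
                                        # "steady": push only the share not inherited
                                        # through the believed dynamics

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.true_internal.copy(), self.decoder.copy(), self.baseline_rates.copy(),
            self.null_sigma, None if self.noise_corr is None else self.noise_corr.copy(),
            self.aim_mode, self.spike_noise, self.push_policy,
        )


def default_mapping(spec: SessionSpec, seed: Optional[int] = None) -> BMIMapping:
    """A generic intuitive decoder: random-direction pushing vectors.

    Unit pushing directions are drawn uniformly with moderate magnitude
    spread, and the offset cancels baseline firing.  Scaled so a typical
    population push attains the session's speed range.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    q = spec.n_units
    ang = rng.uniform(0, 2 * np.pi, q)
    mag = rng.uniform(0.5, 1.5, q)
    Bv = np.vstack([np.cos(ang) * mag, np.sin(ang) * mag])
    # Scale: a coherent half-count/unit push along a direction reaches ~max_speed,
    # so single-timestep commands carry usable direction signal above Poisson noise
    push = np.linalg.norm(Bv, axis=0).mean() * q / 2
    Bv *= spec.max_speed / push
    baseline = rng.uniform(1.5, 4.0, q)
    bv = -Bv @ baseline
    m = BMIMapping(Bv, bv, dt=spec.dt)
    m.provenance = {
        "synthetic": {"seed": spec.seed if seed is None else seed},
        "baseline_rates": baseline.tolist(),
    }
    return m


def _null_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis (q, q-2) of the null space of a 2 x q readout."""
    return scipy.linalg.null_space(M)


def make_ground_truth(
    spec: SessionSpec,
    mismatch: MismatchSpec = MismatchSpec(),
    seed: int = 0,
    mapping: Optional[BMIMapping] = None,
    null_sigma: float = 0.5,
    noise_corr: Optional[np.ndarray] = None,
    aim_mode: str = "internal",
) -> GroundTruth:
    """Build the generative subject for a session.

    The believed readout starts from the decoder's (per-timestep-equivalent)
    pushing vectors and applies the mismatch: global rotation, per-unit gain
    jitter, then additive null-space components.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    decoder = mapping if mapping is not None else default_mapping(spec)
    q = decoder.n_units
    base = decoder_equivalent_internal(decoder, tau=spec.tau)
    Bv = base.Bv.copy()
    bv = base.bv.copy()
    if mismatch.rotation != 0.0:
        R = rotation_matrix(mismatch.rotation)
        Bv = R @ Bv
        bv = R @ bv
    if mismatch.gain_jitter != 0.0:
        g = 1.0 + mismatch.gain_jitter * rng.standard_normal(q)
        Bv = Bv * g
    if mismatch.null_scale != 0.0:
        N = _null_basis(decoder.Bv)
        scale = mismatch.null_scale * np.linalg.norm(base.Bv, axis=0).mean()
        Z = rng.standard_normal((2, N.shape[1]))
        Z *= scale / max(np.linalg.norm(Z, axis=0).mean(), 1e-12)
        Bv = Bv + Z @ N.T
    true_internal = replace(base, Bv=Bv, bv=bv)
    # The subject's baseline firing is the level the decoder offset cancels,
    # so quiescent activity decodes to (and is believed to produce) zero
    # velocity; falls back to a seeded draw for externally supplied mappings.
    prov_base = decoder.provenance.get("baseline_rates")
    if prov_base is not None:
        baseline = np.asarray(prov_base, dtype=float)
    else:
        baseline = rng.uniform(1.5, 4.0, q)
    return GroundTruth(
        true_internal=true_internal, decoder=decoder, baseline_rates=baseline,
        null_sigma=null_sigma, noise_corr=noise_corr, aim_mode=aim_mode,
    )


def _draw_counts(rates: np.ndarray, corr: Optional[np.ndarray], rng) -> np.ndarray:
    """Poisson counts, optionally correlated through a Gaussian copula."""
    if corr is None:
        return rng.poisson(rates)
    from scipy.stats import norm, poisson

    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))
    z = L @ rng.standard_normal(len(rates))
    u = norm.cdf(z)
    return poisson.ppf(u, rates).astype(int)


@dataclass
class _TrialLog:
    clipped_steps: int = 0
    total_steps: int = 0


def _simulate_trial(
    gt: GroundTruth,
    spec: SessionSpec,
    target: np.ndarray,
    rng: np.random.Generator,
    trial_id: int,
    block: str,
) -> Tuple[Trial, _TrialLog]:
    model = gt.true_internal
    dec = gt.decoder
    tau = spec.tau
    q = dec.n_units
    Bpinv = np.linalg.pinv(model.Bv)
    Nbasis = _null_basis(model.Bv)
    contact = spec.cursor_radius + spec.target_radius
    log = _TrialLog()

    nb_dec = _null_basis(dec.Bv)
    Bpinv_dec = np.linalg.pinv(dec.Bv)

    hold = int(rng.integers(spec.hold_steps[0], spec.hold_steps[1] + 1))
    t_on = hold
    T_max = t_on + spec.timeout_steps

    pos: List[np.ndarray] = [np.zeros(2)]
    vel: List[np.ndarray] = []
    raws: List[np.ndarray] = []
    acquired = None
    held = 0
    run_start = None
    t = 0
    while t < T_max:
        if t > 0:
            pos.append(pos[t - 1] + vel[t - 1] * spec.dt)
        aim_target = target if t >= t_on + spec.sensory_delay else np.zeros(2)

        a = max(0, t - tau)
        anchor_v = vel[a] if a < t else np.zeros(2)
        if gt.aim_mode == "feedback":
            # no internal tracking: aim straight from delayed feedback position
            p_belief = pos[a]
            v_prev_belief = anchor_v
        else:
            # unroll the believed model through already-issued raw commands
            U_hist = np.asarray(raws[a + 1: t], dtype=float).reshape(-1, q)
            vels = unroll_velocities(model, anchor_v, U_hist)
            all_v = np.vstack([anchor_v[None], vels])  # v~_a .. v~_{t-1}
            n_steps = t - a
            p_belief = pos[a] + spec.dt * all_v[:n_steps].sum(axis=0)
            v_prev_belief = all_v[-1] if n_steps > 0 else anchor_v

        d = aim_target - p_belief
        dist = float(np.linalg.norm(d))
        if dist > 1e-9:
            v_star = spec.intended_speed(dist) * d / dist
        else:
            v_star = np.zeros(2)

        if gt.aim_mode == "feedback":
            # desired single-timestep command through the believed
            # instantaneous readout (decoder-equivalent, unsmoothed form)
            y = v_star - dec.bv
            mean = gt.baseline_rates + Bpinv_dec @ (y - dec.Bv @ gt.baseline_rates)
            nb = nb_dec
        else:
            # "compensate": the neural push cancels the believed dynamics so
            # the velocity belief equals v* each step; "steady": push only
            # the share not inherited through the believed dynamics, so the
            # belief pursues v*.  An acceleration limit (scaled by the
            # believed smoothing, so the reachable steady-state speed is
            # push_saturation regardless of Av) bounds any one push.
            if gt.push_policy == "steady":
                e = (np.eye(2) - model.Av) @ v_star
            else:
                e = v_star - model.Av @ v_prev_belief
            e_cap = spec.push_saturation * max(1.0 - 0.5 * float(np.trace(model.Av)), 0.05)
            enorm = float(np.linalg.norm(e))
            if enorm > e_cap:
                e = e * (e_cap / enorm)
            y = e - model.bv
            mean = gt.baseline_rates + Bpinv @ (y - model.Bv @ gt.baseline_rates)
            nb = Nbasis
        if gt.null_sigma > 0 and nb.shape[1] > 0:
            mean = mean + nb @ (gt.null_sigma * rng.standard_normal(nb.shape[1]))

        log.total_steps += 1
        if np.any(mean < -1e-9):
            log.clipped_steps += 1
        rates = np.maximum(mean, 0.0)
        if gt.spike_noise == "none":
            u_raw = rates
        else:
            u_raw = _draw_counts(rates, gt.noise_corr, rng)
        raws.append(np.asarray(u_raw, dtype=float))

        u_s = smooth_counts(raws, dec.smooth_window)
        vel.append(decode_velocity(u_s, dec))

        if t >= t_on and np.linalg.norm(pos[t] - target) <= contact:
            if run_start is None:
                run_start = t
            held += 1
            if held >= spec.target_hold_steps:
                acquired = run_start
                break
        else:
            held = 0
            run_start = None
        t += 1

    trial = Trial(
        trial_id=trial_id,
        target=target,
        block=block,
        success=acquired is not None,
        target_onset=t_on,
        acquisition=acquired,
        pos=np.asarray(pos),
        vel=np.asarray(vel),
        spikes_raw=np.asarray(
            raws, dtype=int if gt.spike_noise == "poisson" else float
        ),
    )
    return trial, log


def simulate_session(
    gt: GroundTruth,
    spec: SessionSpec,
    seed: int = 0,
    block: str = "intuitive",
    trial_id_start: int = 0,
    target_order: Optional[Sequence[int]] = None,
) -> Session:
    """Generate a full session under a fixed ground truth.

    Targets are presented in seeded pseudorandom order with each target
    appearing ``trials_per_target`` times.  Fully reproducible from
    ``(gt, spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    targets = spec.target_positions()
    if target_order is None:
        order = np.repeat(np.arange(spec.n_targets), spec.trials_per_target)
        rng.shuffle(order)
    else:
        order = np.asarray(target_order, dtype=int)
    trials = []
    clipped = total = 0
    for i, ti in enumerate(order):
        tr, tlog = _simulate_trial(gt, spec, targets[ti], rng, trial_id_start + i, block)
        trials.append(tr)
        clipped += tlog.clipped_steps
        total += tlog.total_steps
    session = Session(
        dt=spec.dt,
        unit_labels=[f"u{i:03d}" for i in range(spec.n_units)],
        mappings={block: gt.decoder},
        trials=trials,
        provenance={
            "simulated": {
                "seed": seed,
                "clip_rate": clipped / max(total, 1),
                "aim_mode": gt.aim_mode,
            }
        },
    )
    session.attach_smoothed()
    return session


def _drift_toward(model: InternalModel, target: InternalModel, rate: float) -> InternalModel:
    """Exponential per-trial drift of the believed model toward a target model."""
    return replace(
        model,
        Av=model.Av + rate * (target.Av - model.Av),
        Bv=model.Bv + rate * (target.Bv - model.Bv),
        bv=model.bv + rate * (target.bv - model.bv),
    )


def simulate_perturbation_experiment(
    gt: GroundTruth,
    spec: SessionSpec,
    perturbation: PerturbationSpec,
    adaptation_rate: float = 0.0,
    block_trials: Tuple[int, int, int] = (96, 160, 96),
    seed: int = 0,
) -> Session:
    """Intuitive / perturbation / washout experiment with optional learning.

    The decoder is perturbed between blocks; after every trial the subject's
    believed model drifts toward the decoder-equivalent model of the *active*
    mapping at the exponential ``adaptation_rate`` (0 = static subject).
    Washout is skipped if its trial count is 0.
    """
    rng = np.random.default_rng(seed)
    targets = spec.target_positions()
    intuitive = gt.decoder
    perturbed = perturb_mapping(intuitive, perturbation)
    blocks = [("intuitive", intuitive, block_trials[0]),
              ("perturbation", perturbed, block_trials[1])]
    if block_trials[2] > 0:
        blocks.append(("washout", intuitive, block_trials[2]))

    state = gt.copy()
    all_trials: List[Trial] = []
    mappings = {}
    tid = 0
    clipped = total = 0
    for label, mapping, n in blocks:
        mappings[label] = mapping
        state.decoder = mapping
        drift_target = decoder_equivalent_internal(mapping, tau=spec.tau)
        order = np.repeat(np.arange(spec.n_targets), int(np.ceil(n / spec.n_targets)))[:n]
        rng.shuffle(order)
        for ti in order:
            tr, tlog = _simulate_trial(state, spec, targets[ti], rng, tid, label)
            all_trials.append(tr)
            tid += 1
            clipped += tlog.clipped_steps
            total += tlog.total_steps
            if adaptation_rate > 0:
                state.true_internal = _drift_toward(
                    state.true_internal, drift_target, adaptation_rate
                )
    session = Session(
        dt=spec.dt,
        unit_labels=[f"u{i:03d}" for i in range(spec.n_units)],
        mappings=mappings,
        trials=all_trials,
        provenance={
            "simulated": {
                "seed": seed,
                "clip_rate": clipped / max(total, 1),
                "adaptation_rate": adaptation_rate,
                "perturbation": {
                    "rotation_angle": perturbation.rotation_angle,
                    "unit_fraction": perturbation.unit_fraction,
                    "seed": perturbation.seed,
                },
            }
        },
    )
    session.attach_smoothed()
    return session
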