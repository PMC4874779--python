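"""Extraction of a subject's internal forward model from population activity.

The subject is assumed to track the cursor internally: at each timestep ``t``
it grounds its belief at the most recent visual feedback ``x_{t-tau}``
(position and velocity, delayed by the visuomotor latency ``tau``) and rolls
its internal model forward through the raw spike counts it has issued since,

    p~_k = p~_{k-1} + v~_{k-1} * dt                       (deterministic)
    v~_k = Av @ v~_{k-1} + Bv @ u_k^raw + bv + w_k,       w_k ~ N(0, w I)

for ``k = t-tau+1, ..., t``.  The resulting tau-step sequence of predicted
states is the *whisker*.  Straight-to-target aiming ties the whisker to the
trial target G through a single Gaussian observation per timestep,

    G = p~_t + alpha_t * v~_t + r_t,                      r_t ~ N(0, r I),

where ``alpha_t >= 0`` is a per-timestep distance scale that leaves intended
speed unconstrained.  Because the position recursion is noise-free, the only
latent variables in a whisker are its tau 2-D velocities; positions are
affine functions of them.  Whiskers at different timesteps carry independent
latents, so exact inference is per-whisker joint-Gaussian conditioning, and
all model parameters have closed-form M-step updates.

Held-out prediction never uses the target or the aiming equation: a whisker
on test data is the noise-free unrolling of the fitted model from feedback
(the expected internal state given feedback and spikes alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .bmi import BMIMapping, CursorState
from .geometry import ErrorConfig, angular_error
from .session import Session, Trial

__all__ = [
    "InternalModel",
    "Whisker",
    "PosteriorMoments",
    "TrainingSet",
    "FoldAssignment",
    "EMResult",
    "build_whisker",
    "unroll_velocities",
    "e_step",
    "m_step",
    "fit_em",
    "fit_neural_only",
    "fit_on_behavior",
    "fit_aim_from_feedback",
    "make_folds",
    "predict_heldout",
    "movement_onset",
    "decoder_equivalent_internal",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


class NumericalConditioningError(RuntimeError):
    """A whisker posterior became numerically non-PSD."""


class NoOnsetError(ValueError):
    """The cursor never moved toward the target."""


@dataclass
class InternalModel:
    """The subject-side forward model of the cursor.

    ``Av`` (2x2) is the believed velocity dynamics (temporal smoothing),
    ``Bv`` (2xq) the believed per-unit pushing vectors, ``bv`` (2,) the
    believed velocity offset; ``w_var``/``r_var`` are the isotropic process
    and aiming noise variances; ``tau`` the visuomotor delay in timesteps.
    """

    Av: np.ndarray
    Bv: np.ndarray
    bv: np.ndarray
    w_var: float
    r_var: float
    tau: int = 3
    dt: float = 0.033
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Av = np.asarray(self.Av, dtype=float).reshape(2, 2)
        self.Bv = np.asarray(self.Bv, dtype=float)
        self.bv = np.asarray(self.bv, dtype=float).reshape(2)
        if self.w_var <= 0 or self.r_var <= 0:
            raise ValueError("noise variances must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    @property
    def n_units(self) -> int:
        return self.Bv.shape[1]

    def state_space(self):
        """Full (A, B, b) of the internal model over x = [p; v]."""
        q = self.n_units
        A = np.zeros((4, 4))
        A[:2, :2] = np.eye(2)
        A[:2, 2:] = np.eye(2) * self.dt
        A[2:, 2:] = self.Av
        B = np.vstack([np.zeros((2, q)), self.Bv])
        b = np.concatenate([np.zeros(2), self.bv])
        return A, B, b

    def copy(self) -> "InternalModel":
        return replace(
            self, Av=self.Av.copy(), Bv=self.Bv.copy(), bv=self.bv.copy(),
            meta=dict(self.meta),
        )


def decoder_equivalent_internal(mapping: BMIMapping, tau: int = 3) -> InternalModel:
    """Internal model equivalent to the decoder.

    With ``smooth_window == 1`` the correspondence is exact (Av = 0,
    Bv, bv as in the mapping).  For a boxcar window W > 1 the boxcar is not
    in the AR(1) family; the steady-state-equivalent AR(1) surrogate is
    Av = (1 - 1/W) I, Bv/W, bv/W, which matches the boxcar's gain for
    sustained activity.
    """
    W = mapping.smooth_window
    if W == 1:
        Av = np.zeros((2, 2))
        return InternalModel(Av, mapping.Bv.copy(), mapping.bv.copy(),
                             w_var=1e-9, r_var=1e-9, tau=tau, dt=mapping.dt)
    a = 1.0 - 1.0 / W
    return InternalModel(np.eye(2) * a, mapping.Bv / W, mapping.bv / W,
                         w_var=1e-9, r_var=1e-9, tau=tau, dt=mapping.dt)


# ---------------------------------------------------------------------------
# Whiskers
# ---------------------------------------------------------------------------

@dataclass
class Whisker:
    """The tau-step sequence of internal state predictions at one timestep."""

    anchor: CursorState
    positions: np.ndarray   # (tau, 2) predicted positions p~_{t-tau+1..t}
    velocities: np.ndarray  # (tau, 2) predicted velocities v~_{t-tau+1..t}

    @property
    def up_to_date(self) -> CursorState:
        """The subject's current belief (p~_t^t, v~_t^t)."""
        return CursorState(self.positions[-1], self.velocities[-1])


def unroll_velocities(model: InternalModel, v0: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Noise-free velocity recursion from ``v0`` through raw counts ``U`` (K, q)."""
    K = U.shape[0]
    out = np.empty((K, 2))
    v = np.asarray(v0, dtype=float)
    for k in range(K):
        v = model.Av @ v + model.Bv @ U[k] + model.bv
        out[k] = v
    return out


def build_whisker(model: InternalModel, anchor: CursorState, u_raws: np.ndarray) -> Whisker:
    """Deterministic whisker: expected internal states given feedback and spikes.

    ``u_raws`` must hold exactly ``tau`` raw count vectors for timesteps
    ``t-tau+1 ... t``; ``anchor`` is the fed-back cursor state at ``t-tau``.
    The target is never consulted.
    """
    U = np.asarray(u_raws, dtype=float)
    if U.ndim != 2 or U.shape[0] != model.tau:
        raise ValueError(f"expected {model.tau} raw spike vectors, got {U.shape}")
    vel = unroll_velocities(model, anchor.v, U)
    pos = np.empty_like(vel)
    p = anchor.p + anchor.v * model.dt
    pos[0] = p
    for k in range(1, model.tau):
        p = p + vel[k - 1] * model.dt
        pos[k] = p
    return Whisker(anchor=anchor, positions=pos, velocities=vel)


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------

def movement_onset(trial: Trial, dt: float = 0.033) -> int:
    """First timestep at which target-directed cursor speed exceeds 15% of its max.

    The projection is of the cursor velocity onto the center-to-target unit
    vector, evaluated from target onset onward.
    """
    g = trial.target / np.linalg.norm(trial.target)
    proj = trial.vel[trial.target_onset: trial.end + 1] @ g
    if proj.size == 0 or proj.max() <= 0:
        raise NoOnsetError(f"trial {trial.trial_id}: cursor never moved toward target")
    idx = int(np.argmax(proj > 0.15 * proj.max()))
    return trial.target_onset + idx


@dataclass
class TrainingSet:
    """Stacked whisker data: one row per training timestep (whisker)."""

    anchor_p: np.ndarray   # (N, 2)
    anchor_v: np.ndarray   # (N, 2)
    U: np.ndarray          # (N, tau, q) raw counts at t-tau+1..t
    G: np.ndarray          # (N, 2) targets
    trial_ids: np.ndarray  # (N,)
    tau: int
    dt: float

    @property
    def n(self) -> int:
        return len(self.G)

    @property
    def n_units(self) -> int:
        return self.U.shape[2]


def assemble_training_set(
    session: Session,
    trials: Sequence[Trial],
    tau: int,
    features: str = "spikes",
) -> TrainingSet:
    """Collect whisker rows from movement onset through target acquisition.

    ``features="velocity"`` substitutes the 2-D unsmoothed velocity command
    for the q-dimensional raw counts (the low-dimensional behavior control).
    """
    ap, av, UU, GG, ids = [], [], [], [], []
    for tr in trials:
        try:
            onset = movement_onset(tr, session.dt)
        except NoOnsetError:
            continue
        feats = _features_for(session, tr, features)
        for t in range(max(onset, tau), tr.end + 1):
            ap.append(tr.pos[t - tau])
            av.append(tr.vel[t - tau])
            UU.append(feats[t - tau + 1: t + 1])
            GG.append(tr.target)
            ids.append(tr.trial_id)
    if not ids:
        raise ValueError("no usable trials (need >= tau+1 post-onset timesteps)")
    return TrainingSet(
        anchor_p=np.asarray(ap), anchor_v=np.asarray(av), U=np.asarray(UU, dtype=float),
        G=np.asarray(GG), trial_ids=np.asarray(ids), tau=tau, dt=session.dt,
    )


def _features_for(session: Session, trial: Trial, features: str) -> np.ndarray:
    if features == "spikes":
        return np.asarray(trial.spikes_raw, dtype=float)
    if features == "velocity":
        from .bmi import unsmoothed_velocity
        m = session.mapping_for(trial)
        return unsmoothed_velocity(np.asarray(trial.spikes_raw, dtype=float), m)
    raise ValueError(f"unknown feature set {features!r}")


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

@dataclass
class PosteriorMoments:
    """Exact per-whisker posteriors over the latent velocities.

    ``mean`` is (N, tau, 2); ``cov`` is (N, tau, tau, 2, 2) with block
    [j, k] = Cov(v~_{j}, v~_{k}); ``loglik`` is the summed marginal
    log-likelihood of the aiming observations {G}.
    """

    mean: np.ndarray
    cov: np.ndarray
    loglik: float


def _prior_cov_blocks(Av: np.ndarray, w_var: float, tau: int) -> np.ndarray:
    """Chain covariance blocks C[j, k] = Cov(v~_j, v~_k), shape (tau, tau, 2, 2)."""
    C = np.zeros((tau, tau, 2, 2))
    C[0, 0] = w_var * np.eye(2)
    for k in range(1, tau):
        C[k, k] = Av @ C[k - 1, k - 1] @ Av.T + w_var * np.eye(2)
    for j in range(tau):
        for k in range(j + 1, tau):
            C[j, k] = C[j, k - 1] @ Av.T
            C[k, j] = C[j, k].T
    return C


def _prior_means(model: InternalModel, data: TrainingSet) -> np.ndarray:
    """(N, tau, 2) prior velocity means by noise-free recursion from the anchors."""
    N, tau = data.n, data.tau
    M = np.empty((N, tau, 2))
    v = data.anchor_v
    for k in range(tau):
        v = v @ model.Av.T + data.U[:, k] @ model.Bv.T + model.bv
        M[:, k] = v
    return M


def _obs_weights(alphas: np.ndarray, tau: int, dt: float) -> np.ndarray:
    """(N, tau) weights h with G - c = sum_k h_k v~_k + r."""
    N = len(alphas)
    h = np.full((N, tau), dt)
    h[:, tau - 1] = alphas
    return h


def e_step(model: InternalModel, alphas: np.ndarray, data: TrainingSet) -> PosteriorMoments:
    """Condition each whisker's velocity chain on its aiming observation.

    The observation is G = c + sum_k h_k v~_k + r with c = p_{t-tau} +
    dt * v_{t-tau}, h_k = dt for k < tau and h_tau = alpha_t, so the update
    is a rank-2 Gaussian conditioning shared across whiskers (the prior
    covariance depends only on Av and w).
    """
    N, tau = data.n, data.tau
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape != (N,):
        raise ValueError("alphas must have one entry per training timestep")

    C = _prior_cov_blocks(model.Av, model.w_var, tau)       # (tau,tau,2,2)
    M = _prior_means(model, data)                            # (N,tau,2)
    h = _obs_weights(alphas, tau, data.dt)                   # (N,tau)

    c = data.anchor_p + data.dt * data.anchor_v              # (N,2)
    pred = c + np.einsum("nk,nkj->nj", h, M)                 # E[G]
    e = data.G - pred                                        # innovation

    # Czh[n, j] = sum_k h[n,k] C[j,k]  -> Cov(v~_j, h.z)
    Czh = np.einsum("nk,jkab->njab", h, C)                   # (N,tau,2,2)
    S = np.einsum("nj,njab->nab", h, Czh) + model.r_var * np.eye(2)  # (N,2,2)

    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] * S[:, 1, 0]
    if np.any(det <= 0) or not np.all(np.isfinite(det)):
        bad = int(np.argmin(det))
        raise NumericalConditioningError(
            f"non-PSD innovation covariance at whisker {bad}"
        )
    Sinv = np.empty_like(S)
    Sinv[:, 0, 0] = S[:, 1, 1] / det
    Sinv[:, 1, 1] = S[:, 0, 0] / det
    Sinv[:, 0, 1] = -S[:, 0, 1] / det
    Sinv[:, 1, 0] = -S[:, 1, 0] / det

    # Posterior mean: M + Czh @ Sinv @ e
    gain = np.einsum("njab,nbc->njac", Czh, Sinv)            # (N,tau,2,2)
    mean = M + np.einsum("njab,nb->nja", gain, e)

    # Posterior covariance: C[j,k] - gain[j] @ Czh[k].T (per whisker)
    cov = C[None] - np.einsum("njab,nkcb->njkac", gain, Czh)
    # symmetrize blocks (S + S^T)/2 across the (j,a),(k,b) superindex
    cov = 0.5 * (cov + np.transpose(cov, (0, 2, 1, 4, 3)))

    quad = np.einsum("na,nab,nb->n", e, Sinv, e)
    loglik = float(np.sum(-np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad))
    return PosteriorMoments(mean=mean, cov=cov, loglik=loglik)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def m_step(
    moments: PosteriorMoments,
    data: TrainingSet,
    model: InternalModel,
    fix_Av: Optional[np.ndarray] = None,
    ridge: float = 1e-8,
):
    """Closed-form maximizers of the expected complete-data log-likelihood.

    Returns ``(new_model, new_alphas)``.  The dynamics parameters come from
    a joint linear regression of each latent velocity on
    [previous velocity; raw counts; 1]; ``fix_Av`` pins Av (e.g. to 0 for
    the neural-only variant) and drops the previous-velocity regressors.
    Per-timestep ``alpha_t`` is the nonnegatively clamped scalar least
    squares of the aiming residual; ``w`` and ``r`` are isotropic residual
    variances.  ``tau`` is held fixed.
    """
    N, tau, q = data.n, data.tau, data.n_units
    mean, cov = moments.mean, moments.cov
    dt = data.dt

    # Second moments E[v_j v_k^T] including anchor (observed, index -1).
    def Evv(j: int, k: int) -> np.ndarray:
        """(N,2,2) second moment; j,k in {-1, 0..tau-1}; -1 is the anchor."""
        if j == -1 and k == -1:
            return np.einsum("na,nb->nab", data.anchor_v, data.anchor_v)
        if j == -1:
            return np.einsum("na,nb->nab", data.anchor_v, mean[:, k])
        if k == -1:
            return np.einsum("na,nb->nab", mean[:, j], data.anchor_v)
        return cov[:, j, k] + np.einsum("na,nb->nab", mean[:, j], mean[:, k])

    def Ev(j: int) -> np.ndarray:
        return data.anchor_v if j == -1 else mean[:, j]

    use_dyn = fix_Av is None
    d_prev = 2 if use_dyn else 0
    p = d_prev + q + 1
    Sxx = np.zeros((p, p))
    Syx = np.zeros((2, p))
    Syy = np.zeros((2, 2))
    n_trans = N * tau
    for k in range(tau):
        u = data.U[:, k]                      # (N, q)
        ev_prev = Ev(k - 1)
        ev_k = Ev(k)
        if use_dyn:
            Sxx[:2, :2] += Evv(k - 1, k - 1).sum(axis=0)
            Sxx[:2, 2:2 + q] += ev_prev.T @ u
            Sxx[2:2 + q, :2] += u.T @ ev_prev
            Sxx[:2, -1] += ev_prev.sum(axis=0)
            Sxx[-1, :2] += ev_prev.sum(axis=0)
            Syx[:, :2] += Evv(k, k - 1).sum(axis=0)
        Sxx[d_prev:d_prev + q, d_prev:d_prev + q] += u.T @ u
        Sxx[d_prev:d_prev + q, -1] += u.sum(axis=0)
        Sxx[-1, d_prev:d_prev + q] += u.sum(axis=0)
        Sxx[-1, -1] += N
        Syx[:, d_prev:d_prev + q] += ev_k.T @ u
        Syx[:, -1] += ev_k.sum(axis=0)
        Syy += Evv(k, k).sum(axis=0)

    try:
        theta = np.linalg.solve(Sxx, Syx.T).T
    except np.linalg.LinAlgError:
        lam = ridge * np.trace(Sxx) / p
        log.warning("rank-deficient M-step regression; ridge fallback (%.3g)", lam)
        theta = np.linalg.solve(Sxx + lam * np.eye(p), Syx.T).T

    if use_dyn:
        Av_new = theta[:, :2]
        Bv_new = theta[:, 2:2 + q]
    else:
        Av_new = np.asarray(fix_Av, dtype=float).reshape(2, 2)
        Bv_new = theta[:, :q]
    bv_new = theta[:, -1]

    w_new = float(np.trace(Syy - theta @ Syx.T)) / (2 * n_trans)
    w_new = max(w_new, _VAR_FLOOR)

    # alpha_t update: alpha = max(0, E[v_T . d'] / E[|v_T|^2]),
    # d' = G - c - dt * sum_{k<T} v_k
    T = tau - 1
    c = data.anchor_p + dt * data.anchor_v
    gc = data.G - c                                           # (N,2)
    num = np.einsum("na,na->n", mean[:, T], gc)
    den = np.einsum("na,na->n", mean[:, T], mean[:, T]) + np.einsum("naa->n", cov[:, T, T])
    for k in range(T):
        num -= dt * (
            np.einsum("na,na->n", mean[:, T], mean[:, k]) + np.einsum("naa->n", cov[:, T, k])
        )
    alphas_new = np.maximum(0.0, num / np.maximum(den, _VAR_FLOOR))

    # r update with the new alphas: E||gc - sum_k h_k v_k||^2
    h = _obs_weights(alphas_new, tau, dt)                     # (N,tau)
    resid = gc - np.einsum("nk,nka->na", h, mean)
    second = np.einsum("nj,nk,njkaa->n", h, h, cov)
    r_new = float(np.sum(np.einsum("na,na->n", resid, resid) + second)) / (2 * N)
    r_new = max(r_new, _VAR_FLOOR)

    new_model = replace(
        model, Av=Av_new, Bv=Bv_new, bv=bv_new, w_var=w_new, r_var=r_new,
    )
    return new_model, alphas_new


def expected_complete_loglik(
    model: InternalModel, alphas: np.ndarray, moments: PosteriorMoments, data: TrainingSet
) -> float:
    """E_q[log p({v~}, {G} | params)] under posterior moments ``q``.

    Used to verify that each M-step output maximizes the EM surrogate.
    """
    N, tau = data.n, data.tau
    mean, cov = moments.mean, moments.cov
    dt = data.dt

    def Ev(j):
        return data.anchor_v if j == -1 else mean[:, j]

    def Cvv(j, k):
        if j == -1 or k == -1:
            return np.zeros((N, 2, 2))
        return cov[:, j, k]

    total = 0.0
    w, r = model.w_var, model.r_var
    for k in range(tau):
        pred = Ev(k - 1) @ model.Av.T + data.U[:, k] @ model.Bv.T + model.bv
        diff = mean[:, k] - pred
        quad = np.einsum("na,na->n", diff, diff)
        quad += np.einsum("naa->n", Cvv(k, k))
        cross = np.einsum("njab,ab->n", Cvv(k, k - 1)[:, None], model.Av)  # tr(Av C_{k-1,k})
        quad -= 2 * cross
        quad += np.einsum("ab,nbc,ac->n", model.Av, Cvv(k - 1, k - 1), model.Av)
        total += float(np.sum(-np.log(2 * np.pi * w) - quad / (2 * w)))
    h = _obs_weights(np.asarray(alphas, dtype=float), tau, dt)
    c = data.anchor_p + dt * data.anchor_v
    resid = data.G - c - np.einsum("nk,nka->na", h, mean)
    quad = np.einsum("na,na->n", resid, resid) + np.einsum("nj,nk,njkaa->n", h, h, cov)
    total += float(np.sum(-np.log(2 * np.pi * r) - quad / (2 * r)))
    return total


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    model: InternalModel
    alphas: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int


def _default_init(
    mapping: BMIMapping, data: TrainingSet, tau: int, seed: Optional[int], jitter: float,
    features: str = "spikes",
) -> InternalModel:
    """Decoder-equivalent initialization with optional seeded jitter.

    The decoder is the natural prior belief; its AR(1)-equivalent form
    (Av = (1-1/W) I with the readout scaled by 1/W) keeps the initial
    steady-state gain consistent with the smoothing the dynamics encode.
    """
    W = mapping.smooth_window
    if features == "velocity":
        Bv0 = np.eye(2) / W
        bv0 = np.zeros(2)
    else:
        Bv0 = mapping.Bv / W
        bv0 = mapping.bv / W
    Av0 = (1.0 - 1.0 / W) * np.eye(2)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        Bv0 = Bv0 + jitter * np.abs(Bv0).mean() * rng.standard_normal(Bv0.shape)
    vvar = float(np.var(np.linalg.norm(data.anchor_v, axis=1)) + 1.0)
    dvar = float(np.var(np.linalg.norm(data.G - data.anchor_p, axis=1)) + 1.0)
    return InternalModel(
        Av=Av0, Bv=Bv0, bv=bv0, w_var=0.1 * vvar, r_var=0.1 * dvar,
        tau=tau, dt=data.dt,
    )


def _init_alphas(data: TrainingSet) -> np.ndarray:
    dist = np.linalg.norm(data.G - data.anchor_p, axis=1)
    speed = np.maximum(np.linalg.norm(data.anchor_v, axis=1), 1.0)
    return dist / speed


def fit_em(
    session: Session,
    trials: Optional[Sequence[Trial]] = None,
    tau: int = 3,
    max_iter: int = 5000,
    tol: float = 1e-9,
    seed: Optional[int] = None,
    init_jitter: float = 0.0,
    init_model: Optional[InternalModel] = None,
    reset_noise: bool = False,
    fix_Av: Optional[np.ndarray] = None,
    features: str = "spikes",
    mapping: Optional[BMIMapping] = None,
) -> EMResult:
    """Fit the internal model by EM on the given trials (default: all).

    Convergence when the relative log-likelihood change drops below ``tol``
    or the max-abs parameter change drops below 1e-8; hard cap ``max_iter``.
    Deterministic given ``seed`` and the initialization.  Raises a
    diagnostic error if the log-likelihood decreases beyond tolerance.
    """
    trials = list(trials) if trials is not None else list(session.trials)
    data = assemble_training_set(session, trials, tau, features=features)
    if mapping is None:
        mapping = session.mapping_for(trials[0])
    model = init_model.copy() if init_model is not None else _default_init(
        mapping, data, tau, seed, init_jitter, features=features
    )
    if init_model is not None and reset_noise:
        # re-temper the noise scales to the new data: a warm-started model
        # that arrives overconfident (tiny r) can be yanked into a poor
        # local optimum by its first few steps
        vvar = float(np.var(np.linalg.norm(data.anchor_v, axis=1)) + 1.0)
        dvar = float(np.var(np.linalg.norm(data.G - data.anchor_p, axis=1)) + 1.0)
        model = replace(model, w_var=0.1 * vvar, r_var=0.1 * dvar)
    if fix_Av is not None:
        model = replace(model, Av=np.asarray(fix_Av, dtype=float).reshape(2, 2))
    alphas = _init_alphas(data)

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moments = e_step(model, alphas, data)
        trace.append(moments.loglik)
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            denom = max(abs(prev), 1.0)
            rel = (cur - prev) / denom
            if rel < -100 * tol:
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it} ({prev} -> {cur})"
                )
            new_model, new_alphas = m_step(moments, data, model, fix_Av=fix_Av)
            dpar = max(
                np.abs(new_model.Av - model.Av).max(),
                np.abs(new_model.Bv - model.Bv).max(),
                np.abs(new_model.bv - model.bv).max(),
            )
            model, alphas = new_model, new_alphas
            if abs(rel) < tol or dpar < 1e-8:
                converged = True
                break
        else:
            model, alphas = m_step(moments, data, model, fix_Av=fix_Av)
    model.meta.update(
        {"n_iter": it, "final_loglik": trace[-1], "converged": converged,
         "seed": seed, "n_whiskers": data.n}
    )
    return EMResult(
        model=model, alphas=alphas, loglik_trace=np.asarray(trace),
        converged=converged, n_iter=it,
    )


def fit_neural_only(session: Session, trials=None, **kw) -> EMResult:
    """EM with Av pinned to 0: explanatory power from neural structure alone."""
    return fit_em(session, trials, fix_Av=np.zeros((2, 2)), **kw)


def fit_on_behavior(session: Session, trials=None, **kw) -> EMResult:
    """Neural-only variant fit on 2-D cursor velocity commands (negative control)."""
    return fit_em(
        session, trials, fix_Av=np.zeros((2, 2)), features="velocity", **kw
    )


# ---------------------------------------------------------------------------
# Aim-from-feedback alternative (no internal prediction)
# ---------------------------------------------------------------------------

@dataclass
class AimFromFeedbackModel:
    """Linear aiming model: intended velocity regressed on raw counts.

    The subject is assumed to aim straight to the target from the tau-delayed
    feedback position, with intended speed matching the single-timestep
    command speed.  ``predict`` maps raw counts to intended velocities.
    """

    M: np.ndarray  # (2, q)
    m0: np.ndarray  # (2,)
    tau: int

    def predict(self, u_raw: np.ndarray) -> np.ndarray:
        return np.asarray(u_raw, dtype=float) @ self.M.T + self.m0


def fit_aim_from_feedback(
    session: Session, trials: Sequence[Trial], tau: int = 3
) -> AimFromFeedbackModel:
    from .bmi import unsmoothed_velocity

    X, Y = [], []
    for tr in trials:
        m = session.mapping_for(tr)
        try:
            onset = movement_onset(tr, session.dt)
        except NoOnsetError:
            continue
        vraw = unsmoothed_velocity(np.asarray(tr.spikes_raw, dtype=float), m)
        for t in range(max(onset, tau), tr.end + 1):
            d = tr.target - tr.pos[t - tau]
            nd = np.linalg.norm(d)
            if nd == 0:
                continue
            speed = np.linalg.norm(vraw[t])
            X.append(tr.spikes_raw[t].astype(float))
            Y.append(speed * d / nd)
    X = np.column_stack([np.asarray(X), np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(X, np.asarray(Y), rcond=None)
    return AimFromFeedbackModel(M=coef[:-1].T, m0=coef[-1], tau=tau)


# ---------------------------------------------------------------------------
# Cross-validation and held-out prediction
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Per-trial fold index; -1 marks permanent training-only trials."""

    fold_of: dict  # trial_id -> fold index
    n_folds: int

    def test_trials(self, session: Session, fold: int) -> List[Trial]:
        return [t for t in session.trials if self.fold_of.get(t.trial_id) == fold]

    def train_trials(self, session: Session, fold: int) -> List[Trial]:
        return [
            t for t in session.trials
            if t.trial_id in self.fold_of and self.fold_of[t.trial_id] != fold
        ]


def make_folds(session: Session, seed: int = 0, trials: Optional[Sequence[Trial]] = None) -> FoldAssignment:
    """Random fold assignment with one trial per unique target per fold.

    K is the minimum per-target trial count; trials beyond K for any target
    become permanent training-only trials (fold -1).
    """
    rng = np.random.default_rng(seed)
    trials = list(trials) if trials is not None else list(session.trials)
    groups: dict = {}
    for tr in trials:
        key = (round(float(tr.target[0]), 6), round(float(tr.target[1]), 6))
        groups.setdefault(key, []).append(tr)
    K = min(len(g) for g in groups.values())
    fold_of = {}
    for g in groups.values():
        order = rng.permutation(len(g))
        for rank, idx in enumerate(order):
            fold_of[g[idx].trial_id] = rank if rank < K else -1
    return FoldAssignment(fold_of=fold_of, n_folds=K)


@dataclass
class TrialPrediction:
    trial_id: int
    timesteps: np.ndarray         # absolute timestep indices
    whisker_pos: np.ndarray       # (n, 2) up-to-date position beliefs
    whisker_vel: np.ndarray       # (n, 2) up-to-date velocity beliefs
    errors: np.ndarray            # (n,) angular errors, degrees

    @property
    def mean_error(self) -> float:
        return float(self.errors.mean())


def predict_heldout(
    model: InternalModel,
    session: Session,
    trial: Trial,
    config: ErrorConfig = ErrorConfig(),
) -> Optional[TrialPrediction]:
    """Whiskers and angular errors for one held-out trial.

    One whisker per timestep from movement onset through acquisition; the
    target enters only the error scoring, never the whisker construction
    (held-out whiskers are invariant to the trial's stored target).  Returns
    None (with a log entry) if the trial is shorter than tau+1 usable steps.
    """
    tau = model.tau
    try:
        onset = movement_onset(trial, session.dt)
    except NoOnsetError:
        log.info("trial %s skipped: no movement onset", trial.trial_id)
        return None
    t0 = max(onset, tau)
    if trial.end < t0:
        log.info("trial %s skipped: shorter than tau+1 timesteps", trial.trial_id)
        return None
    ts, wp, wv = [], [], []
    for t in range(t0, trial.end + 1):
        anchor = CursorState(trial.pos[t - tau], trial.vel[t - tau])
        wh = build_whisker(model, anchor, trial.spikes_raw[t - tau + 1: t + 1].astype(float))
        ts.append(t)
        wp.append(wh.positions[-1])
        wv.append(wh.velocities[-1])
    wp = np.asarray(wp)
    wv = np.asarray(wv)
    speeds = np.linalg.norm(wv, axis=1)
    ok = speeds > 0
    errors = np.full(len(ts), np.nan)
    if ok.any():
        errors[ok] = angular_error(wp[ok], wv[ok], trial.target, config)
    return TrialPrediction(
        trial_id=trial.trial_id, timesteps=np.asarray(ts),
        whisker_pos=wp, whisker_vel=wv, errors=errors,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: InternalModel, path) -> None:
    doc = {
        "Av": model.Av.tolist(),
        "Bv": model.Bv.tolist(),
        "bv": model.bv.tolist(),
        "w_var": model.w_var,
        "r_var": model.r_var,
        "tau": model.tau,
        "dt": model.dt,
        "meta": {k: (v.item() if isinstance(v, np.generic) else v) for k, v in model.meta.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_model(path) -> InternalModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return InternalModel(
        Av=np.asarray(d["Av"], dtype=float),
        Bv=np.asarray(d["Bv"], dtype=float),
        bv=np.asarray(d["bv"], dtype=float),
        w_var=float(d["w_var"]),
        r_var=float(d["r_var"]),
        tau=int(d["tau"]),
        dt=float(d["dt"]),
        meta=d.get("meta", {}) or {},
    )
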