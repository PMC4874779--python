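"""Figure-level analyses and statistical controls for BMI sessions.

All angular-error aggregation follows the trial-then-session rule: absolute
errors are first averaged within each trial, then averaged across trials.
Each result object records its replication unit and n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bmi import BMIMapping, unsmoothed_velocity, smooth_count_matrix, decode_velocity
from .estimator import (
    InternalModel, FoldAssignment, NoOnsetError, fit_em, movement_onset,
    predict_heldout,
)
from .geometry import ErrorConfig, angular_error, signed_angle
from .session import Session, Trial

__all__ = [
    "detect_latency",
    "lag_error_curve",
    "LagSweepResult",
    "cursor_errors",
    "raw_cursor_errors",
    "internal_model_errors",
    "session_error",
    "fraction_explained",
    "error_histograms",
    "speed_analysis",
    "noise_control",
    "nullspace_shuffle",
    "direction_gaps",
    "adaptation_track",
    "rescaled_pushing_vectors",
]

log = logging.getLogger(__name__)


def _raw_velocities(session: Session, trial: Trial) -> np.ndarray:
    return unsmoothed_velocity(
        np.asarray(trial.spikes_raw, dtype=float), session.mapping_for(trial)
    )


def _safe_errors(origins, directions, target, config) -> np.ndarray:
    """Angular errors with NaN at zero-magnitude commands."""
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    out = np.full(len(origins), np.nan)
    ok = np.linalg.norm(directions, axis=1) > 0
    ok &= np.linalg.norm(target - origins, axis=1) > 0
    if ok.any():
        out[ok] = angular_error(origins[ok], directions[ok], target, config)
    return out


# ---------------------------------------------------------------------------
# Visuomotor latency (error drop after target onset)
# ---------------------------------------------------------------------------

@dataclass
class LatencyResult:
    latency_steps: Optional[int]
    latency_ms: Optional[float]
    table: pd.DataFrame  # per post-onset timestep: mean error, raw and adjusted p
    n_trials: int
    alpha: float


def detect_latency(
    session: Session,
    alpha_level: float = 0.05,
    config: ErrorConfig = ErrorConfig(),
    max_steps: int = 15,
    min_trials: int = 10,
) -> LatencyResult:
    """Latency = first post-onset timestep with a significant error decrease.

    Per-trial baseline is the mean absolute angular error of single-timestep
    velocity commands before target onset; each post-onset timestep is
    compared to baseline across trials with a paired two-sided Wilcoxon
    signed-rank test, Holm-Bonferroni corrected over timesteps.  The
    reported latency (in timesteps) is the 0-based index of the first
    significant decrease; with 1-based bin counting this is the paper-style
    "first decrease at tau+1 timesteps after onset implies latency tau".
    Returns latency None if no significant decrease is found.
    """
    baselines, post = [], []
    for tr in session.trials:
        if tr.target_onset < 1:
            continue
        vraw = _raw_velocities(session, tr)
        pre = _safe_errors(tr.pos[: tr.target_onset], vraw[: tr.target_onset], tr.target, config)
        if np.all(np.isnan(pre)):
            continue
        errs = _safe_errors(
            tr.pos[tr.target_onset: tr.end + 1],
            vraw[tr.target_onset: tr.end + 1],
            tr.target,
            config,
        )
        baselines.append(np.nanmean(pre))
        post.append(errs)
    n_trials = len(baselines)
    baselines = np.asarray(baselines)

    rows = []
    pvals, diffs = [], []
    for k in range(max_steps):
        vals = np.array([p[k] if k < len(p) else np.nan for p in post])
        ok = ~np.isnan(vals)
        if ok.sum() < min_trials:
            break
        d = vals[ok] - baselines[ok]
        try:
            stat = stats.wilcoxon(d, alternative="two-sided")
            p = float(stat.pvalue)
        except ValueError:  # all-zero differences
            p = 1.0
        pvals.append(p)
        diffs.append(float(np.median(d)))
        rows.append({"step": k, "n": int(ok.sum()), "mean_error": float(vals[ok].mean()),
                     "median_diff": diffs[-1], "p_raw": p})
    if not rows:
        return LatencyResult(None, None, pd.DataFrame(), n_trials, alpha_level)

    adj = _holm(np.asarray(pvals))
    table = pd.DataFrame(rows)
    table["p_holm"] = adj
    sig = (table.p_holm < alpha_level) & (table.median_diff < 0)
    if sig.any():
        k = int(table.step[sig].iloc[0])
        return LatencyResult(k, k * session.dt * 1000.0, table, n_trials, alpha_level)
    return LatencyResult(None, None, table, n_trials, alpha_level)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone in raw-p rank)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# Feedback-delay compensation (lag sweep)
# ---------------------------------------------------------------------------

@dataclass
class LagSweepResult:
    lags_steps: np.ndarray
    lags_ms: np.ndarray
    mean_abs_error: np.ndarray
    sem: np.ndarray
    argmin_lag_steps: int
    n_trials: int
    n_timesteps: int


def lag_error_curve(
    session: Session,
    lags_steps: Optional[Sequence[int]] = None,
    config: ErrorConfig = ErrorConfig(),
    velocity_fn=None,
    min_post_onset_ms: float = 100.0,
) -> LagSweepResult:
    """Angular error of single-timestep commands vs the lag of their origin.

    For each lag d the command v_t^raw is evaluated as originating from the
    lagged position p_{t-d}.  Only timesteps for which *every* lag falls
    inside the trial, at least ``min_post_onset_ms`` after target onset, are
    included -- the identical subset at every lag, which controls the
    distance-to-target bias.  ``velocity_fn(session, trial) -> (T, 2)``
    substitutes a different command source (e.g. an aim-from-feedback
    model's predictions); default is the decoder's unsmoothed commands.
    Aggregation is within-trial first, then across trials.
    """
    if lags_steps is None:
        lags_steps = range(-3, 10)  # about -100 .. +300 ms at 33-ms steps
    lags = np.asarray(sorted(lags_steps), dtype=int)
    vfun = velocity_fn or (lambda s, t: _raw_velocities(s, t))
    min_k = int(np.ceil(min_post_onset_ms / 1000.0 / session.dt))

    per_trial = {d: [] for d in lags}
    n_steps = 0
    for tr in session.trials:
        vraw = vfun(session, tr)
        t_lo = max(tr.target_onset + min_k, int(lags.max()))
        t_hi = min(tr.end, tr.end + int(lags.min()))
        ts = [
            t for t in range(t_lo, t_hi + 1)
            if np.linalg.norm(vraw[t]) > 0
        ]
        if not ts:
            continue
        n_steps += len(ts)
        for d in lags:
            origins = np.asarray([tr.pos[t - d] for t in ts])
            dirs = np.asarray([vraw[t] for t in ts])
            errs = _safe_errors(origins, dirs, tr.target, config)
            per_trial[d].append(np.nanmean(errs))
    n_trials = len(per_trial[lags[0]])
    if n_trials == 0:
        raise ValueError("no eligible timesteps for the lag sweep")
    mean = np.array([np.mean(per_trial[d]) for d in lags])
    sem = np.array([np.std(per_trial[d], ddof=1) / np.sqrt(n_trials) for d in lags])
    return LagSweepResult(
        lags_steps=lags, lags_ms=lags * session.dt * 1000.0,
        mean_abs_error=mean, sem=sem,
        argmin_lag_steps=int(lags[np.argmin(mean)]),
        n_trials=n_trials, n_timesteps=n_steps,
    )


# ---------------------------------------------------------------------------
# Session errors through decoder / internal-model views
# ---------------------------------------------------------------------------

def _trial_mean(errors: np.ndarray) -> float:
    return float(np.nanmean(errors))


def cursor_errors(
    session: Session, trials: Optional[Sequence[Trial]] = None,
    config: ErrorConfig = ErrorConfig(),
) -> pd.Series:
    """Per-trial mean absolute angular error of the smoothed cursor velocity."""
    out = {}
    for tr in trials if trials is not None else session.trials:
        try:
            onset = movement_onset(tr, session.dt)
        except NoOnsetError:
            continue
        sl = slice(onset, tr.end + 1)
        errs = _safe_errors(tr.pos[sl], tr.vel[sl], tr.target, config)
        out[tr.trial_id] = _trial_mean(errs)
    return pd.Series(out, name="cursor_error")


def raw_cursor_errors(
    session: Session, trials: Optional[Sequence[Trial]] = None,
    config: ErrorConfig = ErrorConfig(),
) -> pd.Series:
    """Per-trial mean error of single-timestep (unsmoothed) commands from p_t."""
    out = {}
    for tr in trials if trials is not None else session.trials:
        try:
            onset = movement_onset(tr, session.dt)
        except NoOnsetError:
            continue
        vraw = _raw_velocities(session, tr)
        sl = slice(onset, tr.end + 1)
        errs = _safe_errors(tr.pos[sl], vraw[sl], tr.target, config)
        out[tr.trial_id] = _trial_mean(errs)
    return pd.Series(out, name="raw_cursor_error")


def internal_model_errors(
    session: Session,
    models_by_fold: Dict[int, InternalModel],
    folds: FoldAssignment,
    config: ErrorConfig = ErrorConfig(),
    eval_folds: Optional[Sequence[int]] = None,
) -> pd.Series:
    """Per-trial mean error of cross-validated whisker predictions.

    ``models_by_fold[k]`` must have been fit with fold k held out; each
    trial is scored through the model that never saw it.
    """
    out = {}
    for fold in (eval_folds if eval_folds is not None else sorted(models_by_fold)):
        model = models_by_fold[fold]
        for tr in folds.test_trials(session, fold):
            pred = predict_heldout(model, session, tr, config)
            if pred is not None:
                out[tr.trial_id] = pred.mean_error
    return pd.Series(out, name="internal_error")


def session_error(per_trial: pd.Series) -> float:
    """Session-level error: mean over per-trial means."""
    return float(per_trial.mean())


def fraction_explained(cursor: pd.Series, internal: pd.Series) -> float:
    """(cursor - internal) / cursor on the common trial set."""
    common = cursor.index.intersection(internal.index)
    c = session_error(cursor.loc[common])
    i = session_error(internal.loc[common])
    return (c - i) / c


def fit_cv_models(
    session: Session,
    folds: FoldAssignment,
    eval_folds: Optional[Sequence[int]] = None,
    **fit_kw,
) -> Dict[int, InternalModel]:
    """One EM fit per (requested) fold, trained with that fold held out."""
    out = {}
    for fold in (eval_folds if eval_folds is not None else range(folds.n_folds)):
        res = fit_em(session, folds.train_trials(session, fold), **fit_kw)
        res.model.meta["fold"] = fold
        out[fold] = res.model
    return out


def error_histograms(
    views: Dict[str, np.ndarray], bins=None
) -> Dict[str, np.ndarray]:
    """Histogram counts per named error sample (timestep- or trial-level)."""
    if bins is None:
        bins = np.arange(0, 185, 5.0)
    out = {"bin_edges": np.asarray(bins, dtype=float)}
    for name, vals in views.items():
        vals = np.asarray(vals, dtype=float)
        out[name], _ = np.histogram(vals[~np.isnan(vals)], bins=bins)
    return out


# ---------------------------------------------------------------------------
# Speed analysis
# ---------------------------------------------------------------------------

@dataclass
class SpeedResult:
    bin_centers: np.ndarray
    actual_mean: np.ndarray
    actual_sem: np.ndarray
    n_per_bin: np.ndarray
    hold_intended: float
    hold_actual: float
    movement_intended: float
    movement_actual: float
    n_hold: int
    n_movement: int


def speed_analysis(
    session: Session,
    models_by_fold: Dict[int, InternalModel],
    folds: FoldAssignment,
    n_bins: int = 12,
    eval_folds: Optional[Sequence[int]] = None,
) -> SpeedResult:
    """Intended (internal-model) vs actual cursor speed, timestep-by-timestep.

    Intended speed is |v~_t^t| from held-out whiskers; actual is |v_t|.
    The curve bins timesteps by intended speed and reports mean +/- SEM of
    actual speed per bin.  The hold phase comprises all timesteps before
    target onset; the movement phase is, per trial, the single timestep at
    which cursor-to-target distance first drops below 50% of the
    center-to-target distance (trials never crossing are excluded with a
    log entry).
    """
    intended, actual = [], []
    hold_i, hold_a, mov_i, mov_a = [], [], [], []
    for fold in (eval_folds if eval_folds is not None else sorted(models_by_fold)):
        model = models_by_fold[fold]
        tau = model.tau
        for tr in folds.test_trials(session, fold):
            T = tr.end + 1
            ivals = np.full(T, np.nan)
            from .bmi import CursorState
            from .estimator import build_whisker
            for t in range(tau, T):
                anchor = CursorState(tr.pos[t - tau], tr.vel[t - tau])
                wh = build_whisker(model, anchor, tr.spikes_raw[t - tau + 1: t + 1].astype(float))
                ivals[t] = np.linalg.norm(wh.velocities[-1])
            avals = np.linalg.norm(tr.vel[:T], axis=1)
            ok = ~np.isnan(ivals)
            intended.extend(ivals[ok])
            actual.extend(avals[ok])
            pre = ok & (np.arange(T) < tr.target_onset)
            hold_i.extend(ivals[pre])
            hold_a.extend(avals[pre])
            dist = np.linalg.norm(tr.pos[:T] - tr.target, axis=1)
            d0 = np.linalg.norm(tr.target)
            crossed = np.nonzero(dist < 0.5 * d0)[0]
            if crossed.size and ok[crossed[0]]:
                mov_i.append(ivals[crossed[0]])
                mov_a.append(avals[crossed[0]])
            elif not crossed.size:
                log.info("trial %s never crossed 50%% distance; excluded", tr.trial_id)
    intended = np.asarray(intended)
    actual = np.asarray(actual)
    edges = np.linspace(0, max(intended.max(), 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(intended, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    sems = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = actual[sel].mean()
            sems[b] = actual[sel].std(ddof=1) / np.sqrt(counts[b]) if counts[b] > 1 else 0.0
    return SpeedResult(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        actual_mean=means, actual_sem=sems, n_per_bin=counts,
        hold_intended=float(np.mean(hold_i)) if hold_i else np.nan,
        hold_actual=float(np.mean(hold_a)) if hold_a else np.nan,
        movement_intended=float(np.mean(mov_i)) if mov_i else np.nan,
        movement_actual=float(np.mean(mov_a)) if mov_a else np.nan,
        n_hold=len(hold_i), n_movement=len(mov_i),
    )


# ---------------------------------------------------------------------------
# Correlated-noise control (idealized + resampled-noise patterns)
# ---------------------------------------------------------------------------

@dataclass
class NoiseControlResult:
    idealized_decoder_error: float
    idealized_internal_error: float
    noisy_decoder_error: float
    noisy_internal_error: float
    n_idealized: int
    n_simulated: int


def noise_control(
    session: Session,
    models_by_fold: Dict[int, InternalModel],
    folds: FoldAssignment,
    seed: int = 0,
    n_directions: int = 32,
) -> NoiseControlResult:
    """Test whether mismatch could be an artifact of correlated spiking noise.

    Recorded raw patterns are labeled by the nearest of ``n_directions``
    evenly spaced directions (16 targets plus midpoints by default) of their
    decoder-mapped unsmoothed velocity.  Per direction, the idealized
    pattern is the mean of its members; residuals are pooled across
    directions and resampled (with replacement, seeded) to build simulated
    noisy patterns, with per-direction sample counts matched to the data.
    Errors of idealized and simulated patterns are evaluated through the
    decoder and through the cross-validated internal models against the
    direction labels; a simulated pattern is only scored through a model
    whose training data excluded the trial its residual came from.
    """
    rng = np.random.default_rng(seed)
    dirs = np.arange(n_directions) * 360.0 / n_directions
    dir_vecs = np.column_stack([np.cos(np.radians(dirs)), np.sin(np.radians(dirs))])

    mapping = session.mapping_for(session.trials[0])
    pats, labels, trial_of = [], [], []
    for tr in session.trials:
        if tr.trial_id not in folds.fold_of or folds.fold_of[tr.trial_id] < 0:
            continue
        try:
            onset = movement_onset(tr, session.dt)
        except NoOnsetError:
            continue
        vraw = _raw_velocities(session, tr)
        for t in range(onset, tr.end + 1):
            v = vraw[t]
            if np.linalg.norm(v) == 0:
                continue
            ang = np.degrees(np.arctan2(v[1], v[0])) % 360.0
            # nearest direction; ties resolved to the lowest index
            diff = np.abs((dirs - ang + 180.0) % 360.0 - 180.0)
            lab = int(np.argmin(diff))
            pats.append(tr.spikes_raw[t].astype(float))
            labels.append(lab)
            trial_of.append(tr.trial_id)
    pats = np.asarray(pats)
    labels = np.asarray(labels)
    trial_of = np.asarray(trial_of)

    ideal = np.full((n_directions, pats.shape[1]), np.nan)
    resid, resid_trial = [], []
    for i in range(n_directions):
        sel = labels == i
        if not sel.any():
            continue
        ideal[i] = pats[sel].mean(axis=0)
        resid.append(pats[sel] - ideal[i])
        resid_trial.append(trial_of[sel])
    resid = np.vstack(resid)
    resid_trial = np.concatenate(resid_trial)

    def dir_error(vels: np.ndarray, labs: np.ndarray) -> np.ndarray:
        out = np.full(len(labs), np.nan)
        ok = np.linalg.norm(vels, axis=1) > 0
        if ok.any():
            cos = np.einsum("na,na->n", vels[ok], dir_vecs[labs[ok]])
            cos /= np.linalg.norm(vels[ok], axis=1)
            out[ok] = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        return out

    have = ~np.isnan(ideal[:, 0])
    lab_have = np.nonzero(have)[0]
    v_dec = unsmoothed_velocity(ideal[have], mapping)
    ideal_dec = float(np.nanmean(dir_error(v_dec, lab_have)))
    # idealized patterns through each fold model, averaged over folds
    int_errs = []
    for fold, model in models_by_fold.items():
        v_int = ideal[have] @ model.Bv.T + model.bv
        int_errs.append(np.nanmean(dir_error(v_int, lab_have)))
    ideal_int = float(np.mean(int_errs))

    # simulated noisy patterns, counts matched per direction
    noisy_dec, noisy_int = [], []
    n_sim = 0
    for i in lab_have:
        n_i = int((labels == i).sum())
        draw = rng.integers(0, len(resid), size=n_i)
        sims = ideal[i] + resid[draw]
        n_sim += n_i
        vels = unsmoothed_velocity(sims, mapping)
        noisy_dec.append(np.nanmean(dir_error(vels, np.full(n_i, i))))
        src_fold = np.array([folds.fold_of[t] for t in resid_trial[draw]])
        errs = np.full(n_i, np.nan)
        for fold, model in models_by_fold.items():
            sel = src_fold == fold
            if sel.any():
                v_int = sims[sel] @ model.Bv.T + model.bv
                errs[sel] = dir_error(v_int, np.full(int(sel.sum()), i))
        noisy_int.append(np.nanmean(errs))
    return NoiseControlResult(
        idealized_decoder_error=ideal_dec,
        idealized_internal_error=ideal_int,
        noisy_decoder_error=float(np.mean(noisy_dec)),
        noisy_internal_error=float(np.nanmean(noisy_int)),
        n_idealized=int(have.sum()),
        n_simulated=n_sim,
    )


# ---------------------------------------------------------------------------
# Null-space shuffle control
# ---------------------------------------------------------------------------

def nullspace_shuffle(session: Session, seed: int = 0) -> Session:
    """Permute spike-count components in the decoder readout's null space.

    Row-space components (and hence all decoder-mapped velocities) are
    preserved to machine precision; any structure orthogonal to the readout
    is scrambled across the session's timesteps.  Raises for q <= 2 (empty
    null space).  The returned session carries float-valued counts.
    """
    rng = np.random.default_rng(seed)
    if session.n_units <= 2:
        raise ValueError("null space is empty for q <= 2 units")
    mapping = session.mapping_for(session.trials[0])
    import scipy.linalg as sla

    Nb = sla.null_space(mapping.Bv)  # (q, q-2)
    all_null = []
    for tr in session.trials:
        all_null.append(tr.spikes_raw.astype(float) @ Nb)
    flat = np.vstack(all_null)
    perm = rng.permutation(len(flat))
    shuffled = flat[perm]

    out_trials = []
    pos = 0
    for tr in session.trials:
        T = tr.n_timesteps
        u = tr.spikes_raw.astype(float)
        null_part = u @ Nb
        new_u = u - null_part @ Nb.T + shuffled[pos: pos + T] @ Nb.T
        pos += T
        new_tr = Trial(
            trial_id=tr.trial_id, target=tr.target.copy(), block=tr.block,
            success=tr.success, target_onset=tr.target_onset,
            acquisition=tr.acquisition, pos=tr.pos.copy(), vel=tr.vel.copy(),
            spikes_raw=new_u,
        )
        out_trials.append(new_tr)
    out = Session(
        dt=session.dt, unit_labels=list(session.unit_labels),
        mappings={k: m.copy() for k, m in session.mappings.items()},
        trials=out_trials,
        provenance={**session.provenance, "nullspace_shuffle": {"seed": seed}},
    )
    out.attach_smoothed()
    return out


# ---------------------------------------------------------------------------
# Movement-direction gaps
# ---------------------------------------------------------------------------

@dataclass
class DirectionGapResult:
    gaps: np.ndarray       # degrees, circular (includes wraparound)
    mean_gap: float
    n_directions: int


def direction_gaps(
    session: Session, speed_threshold: float = 0.0
) -> DirectionGapResult:
    """Circular gaps between adjacent observed raw movement directions."""
    angs = []
    for tr in session.trials:
        vraw = _raw_velocities(session, tr)
        sp = np.linalg.norm(vraw, axis=1)
        sel = sp > max(speed_threshold, 0.0)
        sel &= sp > 0
        angs.extend(np.degrees(np.arctan2(vraw[sel, 1], vraw[sel, 0])) % 360.0)
    angs = np.sort(np.asarray(angs))
    if angs.size == 0:
        raise ValueError("no directions above the speed threshold")
    if angs.size == 1:
        gaps = np.array([360.0])
    else:
        gaps = np.diff(angs)
        gaps = np.append(gaps, 360.0 - (angs[-1] - angs[0]))
    return DirectionGapResult(gaps=gaps, mean_gap=float(gaps.mean()), n_directions=angs.size)


# ---------------------------------------------------------------------------
# Adaptation tracking
# ---------------------------------------------------------------------------

def _mapping_whisker_errors(
    session: Session, trial: Trial, mapping: BMIMapping, tau: int,
    config: ErrorConfig,
) -> float:
    """Trial-mean error of counterfactual cursor evolution under ``mapping``.

    A whisker for a BMI mapping unrolls from the fed-back cursor state using
    the mapping's own smoothing of the recorded raw counts; when the mapping
    is the active one this reproduces the displayed trajectory exactly.
    """
    sm = smooth_count_matrix(trial.spikes_raw, mapping.smooth_window)
    vhat = decode_velocity(sm, mapping)
    try:
        onset = movement_onset(trial, session.dt)
    except NoOnsetError:
        return np.nan
    origins, dirs = [], []
    for t in range(max(onset, tau), trial.end + 1):
        p = trial.pos[t - tau].copy()
        v = trial.vel[t - tau]
        p = p + v * session.dt
        for k in range(t - tau + 1, t):
            p = p + vhat[k] * session.dt
        origins.append(p)
        dirs.append(vhat[t])
    if not origins:
        return np.nan
    errs = _safe_errors(np.asarray(origins), np.asarray(dirs), trial.target, config)
    return _trial_mean(errs)


@dataclass
class AdaptationResult:
    rounds: np.ndarray                  # first trial index of each 16-trial round
    error_traces: Dict[str, np.ndarray]  # per-round trial-mean errors (boxcar smoothed)
    signed_traces: Dict[str, np.ndarray]  # mean signed angle model-vs-mapping per round
    blocks: List[str]                    # block label per round


def adaptation_track(
    session: Session,
    config: ErrorConfig = ErrorConfig(),
    window: int = 48,
    step: int = 16,
    boxcar: int = 24,
    tau: int = 3,
    sign_flip: bool = False,
    fit_kw: Optional[dict] = None,
) -> AdaptationResult:
    """Track the internal model through intuitive/perturbation/washout blocks.

    A time-varying internal model is refit every ``step`` trials on the
    ``window`` preceding trials and evaluated on the next ``step`` trials
    (never on its own training window); a late-intuitive model is fit on
    the last ``window`` intuitive trials.  Error traces are computed through
    each BMI mapping (counterfactual whiskers; the active mapping's trace
    equals the cursor error) and through the models, then smoothed with a
    causal ``boxcar``-trial filter.  Signed-angle traces compare the
    time-varying model's velocity predictions with each mapping's smoothed
    velocities; ``sign_flip`` negates angles for counter-clockwise
    perturbations so biases do not cancel across experiments.
    """
    fit_kw = dict(fit_kw or {})
    fit_kw.setdefault("tau", tau)
    trials = session.trials
    n = len(trials)
    intuitive_trials = [t for t in trials if t.block == "intuitive"]
    late_int_res = fit_em(session, intuitive_trials[-window:], **fit_kw)
    late_int = late_int_res.model
    late_ids = {t.trial_id for t in intuitive_trials[-window:]}

    rounds = list(range(window, n - step + 1, step))
    labels = [trials[r].block for r in rounds]
    err_names = list(session.mappings) + ["time_varying", "late_intuitive"]
    per_round_err = {k: [] for k in err_names}
    signed = {k: [] for k in session.mappings}

    prev_model = None
    for r in rounds:
        # multi-start EM per window: a warm start from the previous window's
        # model tracks genuine drift, while a start anchored at the stable
        # late-intuitive model protects against the chain dragging a poor
        # local optimum across block boundaries; keep the better likelihood
        starts = [m for m in (prev_model, late_int) if m is not None]
        fits = [
            fit_em(session, trials[r - window: r], init_model=m,
                   reset_noise=True, **fit_kw)
            for m in starts
        ]
        model = max(fits, key=lambda f: f.loglik_trace[-1]).model
        prev_model = model
        chunk = trials[r: r + step]
        for name, mapping in session.mappings.items():
            errs = [
                _mapping_whisker_errors(session, tr, mapping, tau, config)
                for tr in chunk
            ]
            per_round_err[name].append(np.nanmean(errs))
        tv_errs, li_errs = [], []
        angs = {k: [] for k in session.mappings}
        for tr in chunk:
            pred = predict_heldout(model, session, tr, config)
            if pred is not None:
                tv_errs.append(pred.mean_error)
                # signed angles between unsmoothed readouts: frame-pure
                # comparison of the model's and each mapping's view of the
                # same raw activity (whisker endpoints inherit the active
                # mapping's frame through the fed-back anchor velocity)
                u_raw = tr.spikes_raw[pred.timesteps].astype(float)
                v_model = u_raw @ model.Bv.T + model.bv
                for name, mapping in session.mappings.items():
                    vmap = u_raw @ mapping.Bv.T + mapping.bv
                    ok = (np.linalg.norm(v_model, axis=1) > 1e-9) & (
                        np.linalg.norm(vmap, axis=1) > 1e-9
                    )
                    if ok.any():
                        a = signed_angle(v_model[ok], vmap[ok])
                        angs[name].append(float(np.mean(a)))
            if tr.trial_id not in late_ids:
                lpred = predict_heldout(late_int, session, tr, config)
                if lpred is not None:
                    li_errs.append(lpred.mean_error)
        per_round_err["time_varying"].append(np.nanmean(tv_errs) if tv_errs else np.nan)
        per_round_err["late_intuitive"].append(np.nanmean(li_errs) if li_errs else np.nan)
        for name in session.mappings:
            v = np.nanmean(angs[name]) if angs[name] else np.nan
            signed[name].append(-v if sign_flip else v)

    k = max(1, boxcar // step)

    def smooth(x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, np.nan)
        for i in range(len(x)):
            lo = max(0, i - k + 1)
            seg = x[lo: i + 1]
            if np.any(~np.isnan(seg)):
                out[i] = np.nanmean(seg)
        return out

    return AdaptationResult(
        rounds=np.asarray(rounds),
        error_traces={kk: smooth(v) for kk, v in per_round_err.items()},
        signed_traces={kk: np.asarray(v) for kk, v in signed.items()},
        blocks=labels,
    )


def rescaled_pushing_vectors(model: InternalModel, tol: float = 1e-9) -> np.ndarray:
    """Internal-model pushing vectors rescaled for comparison to the decoder's.

    Columns of the believed readout are scaled by 1 / (1 - trace(Av)/2),
    normalizing out the fraction of each velocity prediction inherited from
    the previous prediction rather than from current neural activity.
    """
    denom = 1.0 - 0.5 * float(np.trace(model.Av))
    if abs(denom) < tol:
        raise ValueError(
            f"degenerate velocity dynamics: trace(Av)/2 == 1 (Av={model.Av.tolist()})"
        )
    return (model.Bv / denom).T.copy()
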