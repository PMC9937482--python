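"""Synthetic study generator: raw eye+head traces over panoramic spheres.

Emulates the behavioural structure of an encoding/recognition experiment on
360-degree scenes: horizon-biased regions of interest (ROIs), fixation
sequences that alternate vMF-jittered plateaus and great-circle saccades,
head trajectories that lag and under-shoot the eye, reduced exploration
during recognition, and a separable image-driven vs participant-idiosyncratic
mixture of fixation targets.

The study design mirrors the common paradigm: every participant encodes
``n_scenes_encoding`` scenes (10 s each), then sees ``n_old`` repeated plus
``n_new`` novel scenes in randomized order and answers old/new.  Responses are
drawn from a logistic model of realized exploration tendency, so more
encoding exploration helps and more recognition exploration hurts, which
reproduces the direction of the usual memory effects.

All randomness descends from a single study seed through
``numpy.random.SeedSequence``, making every dataset bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import expit
from scipy.stats import vonmises_fisher

from . import sphere
from .sphere import FORWARD

__all__ = [
    "SceneModel",
    "ParticipantModel",
    "StudyConfig",
    "RawTrial",
    "StudyData",
    "make_scene",
    "simulate_trial",
    "simulate_study",
]


@dataclass
class SceneModel:
    """ROI stand-in for panoramic image content.

    ROI centers are drawn with longitude uniform and latitude von Mises about
    the horizon (concentration ``horizon_kappa``); each ROI is a vMF component
    with concentration ``roi_concentrations[k]`` and weight ``roi_weights[k]``.
    """

    scene_id: str
    roi_lon: np.ndarray
    roi_lat: np.ndarray
    roi_concentrations: np.ndarray
    roi_weights: np.ndarray
    horizon_kappa: float

    def __post_init__(self):
        self.roi_lon = np.asarray(self.roi_lon, dtype=float)
        self.roi_lat = np.asarray(self.roi_lat, dtype=float)
        self.roi_concentrations = np.asarray(self.roi_concentrations, dtype=float)
        self.roi_weights = np.asarray(self.roi_weights, dtype=float)
        if np.any(self.roi_weights < 0) or abs(self.roi_weights.sum() - 1.0) > 1e-12:
            raise ValueError("ROI weights must be nonnegative and sum to 1")
        if np.any(self.roi_concentrations <= 0):
            raise ValueError("ROI concentrations must be positive")

    @property
    def n_rois(self) -> int:
        return self.roi_lon.size


@dataclass
class ParticipantModel:
    """Idiosyncratic viewing tendencies of one simulated participant.

    ``idiosyncrasy`` is the probability that a fixation target comes from the
    participant's private ROI set rather than the scene's; ``head_gain`` times
    ``mover_scale`` gives the fraction of each target's eccentricity that the
    head actually covers ('movers' vs 'nonmovers').
    """

    participant_id: str
    idiosyncrasy: float
    private_rois: SceneModel
    head_gain: float
    head_lag_ms: float
    mover_scale: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.idiosyncrasy <= 1.0:
            raise ValueError("idiosyncrasy must be in [0, 1]")
        if not 0.0 <= self.head_gain <= 1.0:
            raise ValueError("head_gain must be in [0, 1]")
        if self.head_lag_ms < 0:
            raise ValueError("head_lag_ms must be >= 0")

    @property
    def effective_gain(self) -> float:
        return float(np.clip(self.head_gain * self.mover_scale, 0.0, 1.0))


@dataclass
class StudyConfig:
    """Design and generative parameters of a synthetic study.

    Defaults replicate the reference design: 80 encoding trials, 40 old + 40
    new recognition trials, 10 s stimuli, 250 Hz eye / 70 Hz head sampling,
    gamma fixation durations (shape 4, mean 200 ms).
    """

    n_participants: int = 21
    n_scenes_encoding: int = 80
    n_old: int = 40
    n_new: int = 40
    trial_duration_ms: float = 10_000.0
    eye_rate_hz: float = 250.0
    head_rate_hz: float = 70.0
    fixation_duration_shape: float = 4.0
    fixation_duration_mean_ms: float = 200.0
    min_fixation_ms: float = 100.0
    saccade_base_ms: float = 20.0
    saccade_ms_per_deg: float = 2.0
    max_saccade_ms: float = 60.0
    min_target_separation_deg: float = 5.0
    recognition_roi_fraction: float = 0.5
    noise_kappa: float = 10_000.0
    n_rois_per_scene: int = 8
    roi_kappa: float = 80.0
    horizon_kappa: float = 8.0
    idiosyncrasy: float = 0.2
    n_private_rois: int = 4
    head_gain: float = 0.8
    head_lag_ms: float = 80.0
    mover_scale_range: tuple = (0.7, 1.3)
    response_intercept: float = 2.4
    response_beta_encoding: float = 0.8
    response_beta_recognition: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.eye_rate_hz <= 0 or self.head_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if not 0.0 < self.recognition_roi_fraction <= 1.0:
            raise ValueError("recognition_roi_fraction must be in (0, 1]")
        if self.n_old > self.n_scenes_encoding:
            raise ValueError("n_old cannot exceed the encoding scene pool")
        if self.trial_duration_ms < self.min_fixation_ms:
            raise ValueError("trial shorter than one minimum fixation")


@dataclass
class RawTrial:
    """Raw recordings of one trial plus generator ground truth.

    ``eye_vec`` holds eye-in-head unit vectors at ``eye_t`` (ms); ``head_q``
    holds head orientation quaternions at ``head_t``.  ``gt_lon/gt_lat`` with
    ``gt_on/gt_off`` describe the intended fixation plateaus, which tile
    [0, duration] minus the saccade gaps.  ``response``/``correct`` are filled
    at study level for recognition trials.
    """

    participant_id: str
    scene_id: str
    phase: str  # encoding | recognition_old | recognition_new
    eye_t: np.ndarray
    eye_vec: np.ndarray
    head_t: np.ndarray
    head_q: np.ndarray
    gt_lon: np.ndarray
    gt_lat: np.ndarray
    gt_on: np.ndarray
    gt_off: np.ndarray
    response: Optional[str] = None
    correct: Optional[bool] = None

    @property
    def n_ground_truth(self) -> int:
        return self.gt_lon.size

    def ground_truth_exploration(self) -> float:
        """Mean great-circle distance of each plateau target from the first."""
        if self.gt_lon.size <= 1:
            return 0.0
        d = sphere.angular_distance(
            self.gt_lon[1:], self.gt_lat[1:], self.gt_lon[0], self.gt_lat[0]
        )
        return float(np.mean(d))


@dataclass
class StudyData:
    """A full simulated study: raw trials plus the trial metadata table."""

    config: StudyConfig
    scenes: dict
    participants: dict
    trials: list
    trial_table: "object" = None  # pandas.DataFrame, filled by simulate_study


def _sample_horizon_lat(rng, n, horizon_kappa):
    """Latitudes (deg) ~ von Mises about 0 with concentration kappa, |lat|<=90."""
    if np.isinf(horizon_kappa):
        return np.zeros(n)
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = np.rad2deg(rng.vonmises(0.0, horizon_kappa, size=2 * (n - filled)))
        cand = cand[np.abs(cand) <= 90.0]
        take = min(cand.size, n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def make_scene(seed, n_rois=8, horizon_kappa=8.0, roi_kappa=80.0,
               scene_id=None) -> SceneModel:
    """Draw a scene model: horizon-biased ROI centers with vMF concentrations."""
    if n_rois < 1:
        raise ValueError("need at least one ROI")
    if not horizon_kappa > 0:
        raise ValueError("horizon_kappa must be positive")
    rng = np.random.default_rng(seed)
    lon = sphere.wrap_longitude(rng.uniform(-180.0, 180.0, size=n_rois))
    lat = _sample_horizon_lat(rng, n_rois, horizon_kappa)
    weights = rng.dirichlet(np.full(n_rois, 2.0))
    weights = weights / weights.sum()
    return SceneModel(
        scene_id=scene_id if scene_id is not None else f"scene_{seed}",
        roi_lon=lon,
        roi_lat=lat,
        roi_concentrations=np.full(n_rois, float(roi_kappa)),
        roi_weights=weights,
        horizon_kappa=float(horizon_kappa),
    )


def _vmf_sample(rng, mu_vec, kappa):
    """One vMF draw about unit vector mu; kappa=inf returns mu exactly."""
    if kappa is None or np.isinf(kappa):
        return np.asarray(mu_vec, dtype=float)
    return vonmises_fisher(mu_vec, kappa).rvs(1, random_state=rng)[0]


def _draw_target(rng, scene, participant, eligible_idx, prev_vec, min_sep):
    """Next fixation target: scene-vs-private ROI mixture, >= min_sep away."""
    for _ in range(200):
        if participant.idiosyncrasy > 0 and rng.random() < participant.idiosyncrasy:
            pool = participant.private_rois
            idx = rng.choice(pool.n_rois, p=pool.roi_weights)
        else:
            pool = scene
            w = pool.roi_weights[eligible_idx]
            idx = eligible_idx[rng.choice(eligible_idx.size, p=w / w.sum())]
        mu = sphere.sph_to_vec(pool.roi_lon[idx], pool.roi_lat[idx])
        v = _vmf_sample(rng, mu, pool.roi_concentrations[idx])
        if sphere._vec_angular_distance(v, prev_vec) >= min_sep:
            return v
    raise RuntimeError("could not draw a target far enough from the previous one")


def _plan_trial(rng, scene, participant, phase, cfg):
    """Lay out plateau/saccade events on [0, duration].

    Returns (targets (n,3), onsets, offsets, sacc_on, sacc_off) where the
    plateaus tile the trial minus saccade gaps.  The final plateau is extended
    to the trial end whenever the remainder could not hold a full saccade plus
    a minimum-duration plateau, so every ground-truth plateau is detectable.
    """
    dur = cfg.trial_duration_ms
    scale = cfg.fixation_duration_mean_ms / cfg.fixation_duration_shape

    n_rois = scene.n_rois
    if phase.startswith("recognition"):
        k = max(1, int(round(cfg.recognition_roi_fraction * n_rois)))
        eligible = rng.choice(n_rois, size=min(k, n_rois), replace=False)
    else:
        eligible = np.arange(n_rois)

    targets = [FORWARD.copy()]  # trial starts on the fixation cross at (0, 0)
    onsets, offsets = [], []
    sacc_on, sacc_off = [], []
    t = 0.0
    reserve = cfg.max_saccade_ms + cfg.min_fixation_ms
    while True:
        d = max(cfg.min_fixation_ms, rng.gamma(cfg.fixation_duration_shape, scale))
        end = t + d
        if dur - end < reserve:
            end = dur
        onsets.append(t)
        offsets.append(end)
        t = end
        if t >= dur:
            break
        nxt = _draw_target(rng, scene, participant, eligible, targets[-1],
                           cfg.min_target_separation_deg)
        amp = sphere._vec_angular_distance(targets[-1], nxt)
        d_sacc = min(cfg.saccade_base_ms + cfg.saccade_ms_per_deg * amp,
                     cfg.max_saccade_ms)
        sacc_on.append(t)
        sacc_off.append(t + d_sacc)
        t += d_sacc
        targets.append(nxt)
    return (np.array(targets), np.array(onsets), np.array(offsets),
            np.array(sacc_on), np.array(sacc_off))


def _gaze_world_at(eye_t, targets, onsets, offsets, sacc_on, sacc_off,
                   rng, noise_kappa):
    """World gaze direction at each eye timestamp (plateau jitter + arcs)."""
    n = eye_t.size
    out = np.empty((n, 3))
    noisy = noise_kappa is not None and np.isfinite(noise_kappa)
    for k in range(len(onsets)):
        sel = (eye_t >= onsets[k]) & (eye_t < offsets[k])
        m = int(sel.sum())
        if m == 0:
            continue
        if noisy:
            out[sel] = vonmises_fisher(targets[k], noise_kappa).rvs(
                m, random_state=rng).reshape(m, 3)
        else:
            out[sel] = targets[k]
    for k in range(len(sacc_on)):
        sel = (eye_t >= sacc_on[k]) & (eye_t < sacc_off[k])
        if not np.any(sel):
            continue
        frac = (eye_t[sel] - sacc_on[k]) / (sacc_off[k] - sacc_on[k])
        out[sel] = sphere.geodesic_point(targets[k], targets[k + 1], frac)
    # samples at/after the last offset (end-of-trial rounding) hold the last target
    tail = eye_t >= offsets[-1]
    if np.any(tail):
        out[tail] = targets[-1]
    return out


def _head_dir_at(t_query, targets, sacc_on, sacc_off, gain, lag):
    """Head direction at query times: under-shot targets, lagged transitions.

    The head target for plateau k sits at fraction ``gain`` along the great
    circle from the trial-start direction to the eye target; the head moves
    between successive head targets during the eye's saccade window shifted by
    ``lag`` ms.
    """
    head_targets = np.array(
        [sphere.geodesic_point(FORWARD, tg, gain) for tg in targets]
    )
    out = np.empty((t_query.size, 3))
    out[:] = head_targets[0]
    for k in range(len(sacc_on)):
        t0, t1 = sacc_on[k] + lag, sacc_off[k] + lag
        moving = (t_query >= t0) & (t_query < t1)
        if np.any(moving):
            frac = (t_query[moving] - t0) / (t1 - t0)
            out[moving] = sphere.geodesic_point(
                head_targets[k], head_targets[k + 1], frac)
        out[t_query >= t1] = head_targets[k + 1]
    return out


def simulate_trial(scene: SceneModel, participant: ParticipantModel, phase: str,
                   config: StudyConfig, seed) -> RawTrial:
    """Simulate one trial's raw eye-in-head and head-quaternion streams.

    The recorded eye-in-head vector is the inverse head rotation (as later
    slerp-interpolated from the 70 Hz head stream) applied to the world gaze
    direction, so the preprocessing stage reconstructs the world gaze exactly.
    """
    if phase not in ("encoding", "recognition_old", "recognition_new"):
        raise ValueError(f"unknown phase: {phase}")
    rng = np.random.default_rng(seed)
    cfg = config
    dur = cfg.trial_duration_ms

    targets, onsets, offsets, sacc_on, sacc_off = _plan_trial(
        rng, scene, participant, phase, cfg)

    eye_t = np.arange(0.0, dur, 1000.0 / cfg.eye_rate_hz)
    head_t = np.arange(0.0, dur, 1000.0 / cfg.head_rate_hz)

    gaze_world = _gaze_world_at(eye_t, targets, onsets, offsets,
                                sacc_on, sacc_off, rng, cfg.noise_kappa)

    head_dir = _head_dir_at(head_t, targets, sacc_on, sacc_off,
                            participant.effective_gain, participant.head_lag_ms)
    head_q = sphere.quat_between(np.broadcast_to(FORWARD, head_dir.shape), head_dir)

    # eye-in-head via the same slerp the preprocessing stage will apply
    from .preprocess import interpolate_head  # local import avoids a cycle

    q_at_eye = interpolate_head(head_t, head_q, eye_t)
    eye_vec = sphere.quat_rotate(sphere.quat_conjugate(q_at_eye), gaze_world)

    gt_lon, gt_lat = sphere.vec_to_sph(targets)
    return RawTrial(
        participant_id=participant.participant_id,
        scene_id=scene.scene_id,
        phase=phase,
        eye_t=eye_t,
        eye_vec=eye_vec,
        head_t=head_t,
        head_q=head_q,
        gt_lon=np.atleast_1d(gt_lon),
        gt_lat=np.atleast_1d(gt_lat),
        gt_on=onsets,
        gt_off=offsets,
    )


def _make_participant(pid, cfg, seed_roi, mover_scale) -> ParticipantModel:
    private = make_scene(seed_roi, n_rois=cfg.n_private_rois,
                         horizon_kappa=cfg.horizon_kappa, roi_kappa=cfg.roi_kappa,
                         scene_id=f"{pid}_private")
    return ParticipantModel(
        participant_id=pid,
        idiosyncrasy=cfg.idiosyncrasy,
        private_rois=private,
        head_gain=cfg.head_gain,
        head_lag_ms=cfg.head_lag_ms,
        mover_scale=mover_scale,
    )


def simulate_study(config: StudyConfig, seed=None) -> StudyData:
    """Simulate a full study and assign old/new responses.

    Encoding block covers all encoding scenes; the recognition block presents
    the ``n_old`` repeated scenes (R-set) and ``n_new`` novel scenes in
    randomized order.  Per-trial seeds derive deterministically from the study
    seed.  Correctness is drawn from a logistic model: baseline log-odds
    ``response_intercept``, plus ``response_beta_encoding`` times the z-scored
    encoding exploration (old scenes only), minus ``response_beta_recognition``
    times the z-scored recognition exploration.
    """
    import pandas as pd

    cfg = config
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    enc_scene_ids = [f"S{i:03d}" for i in range(cfg.n_scenes_encoding)]
    new_scene_ids = [f"N{i:03d}" for i in range(cfg.n_new)]
    scene_seeds = ss.spawn(len(enc_scene_ids) + len(new_scene_ids))
    scenes = {
        sid: make_scene(s, n_rois=cfg.n_rois_per_scene,
                        horizon_kappa=cfg.horizon_kappa, roi_kappa=cfg.roi_kappa,
                        scene_id=sid)
        for sid, s in zip(enc_scene_ids + new_scene_ids, scene_seeds)
    }
    r_set = sorted(rng.choice(enc_scene_ids, size=cfg.n_old, replace=False))
    d_set = sorted(set(enc_scene_ids) - set(r_set))

    part_seeds = ss.spawn(cfg.n_participants)
    participants = {}
    for i, s in enumerate(part_seeds):
        pid = f"P{i:02d}"
        mover = rng.uniform(*cfg.mover_scale_range)
        participants[pid] = _make_participant(pid, cfg, s, mover)

    trials = []
    rows = []
    for pid, part in participants.items():
        enc_order = rng.permutation(enc_scene_ids)
        rec_scenes = [(sid, "recognition_old") for sid in r_set] + \
                     [(sid, "recognition_new") for sid in new_scene_ids]
        rec_order = [rec_scenes[i] for i in rng.permutation(len(rec_scenes))]
        plan = [(sid, "encoding") for sid in enc_order] + rec_order
        trial_seeds = ss.spawn(len(plan))
        for k, ((sid, phase), ts) in enumerate(zip(plan, trial_seeds)):
            trials.append(simulate_trial(scenes[sid], part, phase, cfg, ts))
            rows.append({"participant": pid, "trial": k, "phase": phase,
                         "scene": sid})

    table = pd.DataFrame(rows)
    _assign_responses(trials, table, cfg, np.random.default_rng(ss.spawn(1)[0]))
    table["old_new"] = np.where(
        table["phase"] == "encoding",
        np.where(table["scene"].isin(r_set), "repeated", "dropped"),
        np.where(table["phase"] == "recognition_old", "old", "new"),
    )
    return StudyData(config=cfg, scenes=scenes, participants=participants,
                     trials=trials, trial_table=table)


def _assign_responses(trials, table, cfg, rng):
    expl = np.array([tr.ground_truth_exploration() for tr in trials])
    phase = table["phase"].to_numpy()

    def z(mask):
        x = expl[mask]
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 1e-9 else 1.0)

    z_all = np.zeros_like(expl)
    for ph in ("encoding", "recognition_old", "recognition_new"):
        m = phase == ph
        if m.any():
            z_all[m] = z(m)

    enc_z = {}
    for i, tr in enumerate(trials):
        if tr.phase == "encoding":
            enc_z[(tr.participant_id, tr.scene_id)] = z_all[i]

    responses = np.full(len(trials), None, dtype=object)
    corrects = np.full(len(trials), None, dtype=object)
    for i, tr in enumerate(trials):
        if tr.phase == "encoding":
            continue
        logit = cfg.response_intercept - cfg.response_beta_recognition * z_all[i]
        if tr.phase == "recognition_old":
            logit += cfg.response_beta_encoding * enc_z.get(
                (tr.participant_id, tr.scene_id), 0.0)
        correct = bool(rng.random() < expit(logit))
        truth_old = tr.phase == "recognition_old"
        said_old = correct if truth_old else not correct
        tr.correct = correct
        tr.response = "old" if said_old else "new"
        responses[i] = tr.response
        corrects[i] = correct
    table["response"] = responses
    table["correct"] = corrects
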