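"""Synthetic infant-wearable data generator.

Produces ground-truth posture/movement/carrying state sequences, 4-sensor
IMU signals, multi-rater annotations, and recording-level feature cohorts,
so that every stage of the analysis pipeline can be exercised without
clinical recordings.

The generator encodes the developmental structure the pipeline is built
around: age-dependent category occupancies (prone posture decreasing with
age, standing and fluent movement increasing, crawling transiently
bell-shaped), posture-specific gravity orientations of the four limb
sensors, movement-quality-dependent signal dynamics with overlapping
amplitude tiers, and second-level rater noise (per-class confusion plus
boundary jitter).

State sequences are semi-Markov: states hold for geometrically distributed
dwell times (configurable means per track), and successive states are drawn
with an occupancy-tracking scheduler so that empirical time fractions
converge to the configured age-dependent priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import (
    CARRYING,
    FUSED_MOVEMENTS,
    FUSED_POSTURES,
    GRAVITY,
    MOVEMENT_FUSE_MAP,
    MOVEMENTS,
    POSTURE_FUSE_MAP,
    POSTURES,
    SAMPLE_RATE,
    SENSORS,
)

# --------------------------------------------------------------------------
# Age trajectories
# --------------------------------------------------------------------------
# Each category's (unnormalized) occupancy weight as a function of corrected
# age in months. Two curve families: a logistic ramp for monotone categories
# and a Gaussian bell for developmentally transient ones. Values chosen to
# mirror the qualitative trajectory shapes of typical infant development
# between 4 and 16 months.

DEFAULT_POSTURE_TRAJECTORIES: dict[str, dict] = {
    "supine": dict(kind="logistic", lo=0.02, hi=0.45, mid=8.0, slope=-0.8),
    "prone": dict(kind="logistic", lo=0.03, hi=0.38, mid=9.0, slope=-0.7),
    "side_left": dict(kind="logistic", lo=0.01, hi=0.06, mid=8.0, slope=-0.6),
    "side_right": dict(kind="logistic", lo=0.01, hi=0.06, mid=8.0, slope=-0.6),
    "crawl_posture": dict(kind="bell", base=0.01, amp=0.30, mid=10.0, width=2.5),
    "sitting": dict(kind="bell", base=0.04, amp=0.32, mid=9.0, width=4.0),
    "standing": dict(kind="logistic", lo=0.01, hi=0.60, mid=12.0, slope=0.9),
}

DEFAULT_MOVEMENT_TRAJECTORIES: dict[str, dict] = {
    "still": dict(kind="logistic", lo=0.15, hi=0.45, mid=10.0, slope=-0.6),
    "proto": dict(kind="logistic", lo=0.10, hi=0.35, mid=11.0, slope=-0.6),
    "elementary": dict(kind="bell", base=0.05, amp=0.28, mid=10.0, width=3.0),
    "fluent": dict(kind="logistic", lo=0.02, hi=0.45, mid=12.5, slope=0.9),
    "pivot_left": dict(kind="bell", base=0.005, amp=0.05, mid=8.0, width=2.5),
    "pivot_right": dict(kind="bell", base=0.005, amp=0.05, mid=8.0, width=2.5),
    "roll_left": dict(kind="bell", base=0.005, amp=0.05, mid=7.0, width=2.5),
    "roll_right": dict(kind="bell", base=0.005, amp=0.05, mid=7.0, width=2.5),
    "transition": dict(kind="bell", base=0.02, amp=0.08, mid=11.0, width=3.0),
}

#: Age-independent carrying-track prior (independent play dominates).
DEFAULT_CARRYING_PRIOR: dict[str, float] = {
    "independent": 0.86,
    "passive_support": 0.05,
    "active_support": 0.04,
    "passive_carry": 0.02,
    "active_carry": 0.03,
}

#: Movement classes physically compatible with each posture (e.g., no
#: fluent locomotion while lying supine; rolling only from lying postures).
ALLOWED_MOVEMENTS: dict[str, tuple[str, ...]] = {
    "supine": ("still", "proto", "elementary", "roll_left", "roll_right", "transition"),
    "prone": (
        "still", "proto", "elementary", "fluent",
        "pivot_left", "pivot_right", "roll_left", "roll_right", "transition",
    ),
    "side_left": ("still", "proto", "elementary", "roll_left", "roll_right", "transition"),
    "side_right": ("still", "proto", "elementary", "roll_left", "roll_right", "transition"),
    "crawl_posture": ("still", "proto", "elementary", "fluent", "transition"),
    "sitting": ("still", "proto", "elementary", "fluent", "transition"),
    "standing": ("still", "proto", "elementary", "fluent", "transition"),
}

# Per-posture accelerometer gravity direction for each sensor (unit
# vectors, sensor frame). A fixed, documented convention: it gives each
# posture a distinct 12-dimensional static accelerometer signature.
_ARMS = ("left_arm", "right_arm")
_LEGS = ("left_leg", "right_leg")


def _orient(arm_vec, leg_vec):
    arm = np.asarray(arm_vec, float)
    leg = np.asarray(leg_vec, float)
    arm = arm / np.linalg.norm(arm)
    leg = leg / np.linalg.norm(leg)
    table = {s: arm for s in _ARMS}
    table.update({s: leg for s in _LEGS})
    return table


GRAVITY_ORIENTATION: dict[str, dict[str, np.ndarray]] = {
    "supine": _orient((0, 0, 1), (0, 0, 1)),
    "prone": _orient((0, 0, -1), (0, 0, -1)),
    "side_left": _orient((0, 1, 0), (0, 1, 0)),
    "side_right": _orient((0, -1, 0), (0, -1, 0)),
    "crawl_posture": _orient((0.6, 0, -0.8), (0.8, 0, 0.6)),
    "sitting": _orient((1, 0, 0), (0, 0, 1)),
    "standing": _orient((1, 0, 0), (1, 0, 0)),
}

#: Movement-quality signal dynamics: (accel oscillation SD in m/s^2,
#: gyro oscillation SD in deg/s). Tiers increase still < proto <
#: elementary < fluent; per-segment amplitudes are drawn lognormally
#: around the tier so neighbouring tiers overlap (mirroring the lower
#: human agreement on movement than on posture).
MOVEMENT_AMPLITUDE: dict[str, tuple[float, float]] = {
    "still": (0.0, 0.0),
    "proto": (0.5, 20.0),
    "elementary": (1.1, 45.0),
    "fluent": (2.2, 90.0),
    "pivot_left": (0.8, 60.0),
    "pivot_right": (0.8, 60.0),
    "roll_left": (1.5, 80.0),
    "roll_right": (1.5, 80.0),
    "transition": (1.8, 70.0),
}

#: Lognormal sigma for per-segment amplitude draws.
AMPLITUDE_SIGMA = 0.35

#: Common-mode adult-gait oscillation added while carried:
#: (frequency Hz, accel amplitude m/s^2) per carrying class.
CARRY_SIGNATURE: dict[str, tuple[float, float]] = {
    "active_carry": (2.0, 2.5),
    "passive_carry": (0.5, 0.8),
}


@dataclass
class NoiseParams:
    """Sensor noise model parameters."""

    accel_noise_sd: float = 0.25      # m/s^2 per-sample white noise
    gyro_noise_sd: float = 1.5        # deg/s per-sample white noise
    gyro_bias_range: float = 3.0      # deg/s, per-channel bias ~ U(-range, range)
    packet_jitter_sd: float = 0.002   # s, timestamp jitter
    packet_drop_p: float = 0.01       # per-packet drop probability


@dataclass
class DwellParams:
    """Mean dwell times (s) of the semi-Markov state generator."""

    posture_s: float = 15.0
    movement_s: float = 4.5
    carrying_s: float = 8.0


@dataclass
class SimConfig:
    """Configuration of a synthetic recording."""

    age_months: float = 10.0
    duration_s: float = 600.0
    seed: int = 0
    posture_trajectories: dict = field(
        default_factory=lambda: dict(DEFAULT_POSTURE_TRAJECTORIES))
    movement_trajectories: dict = field(
        default_factory=lambda: dict(DEFAULT_MOVEMENT_TRAJECTORIES))
    carrying_prior: dict = field(
        default_factory=lambda: dict(DEFAULT_CARRYING_PRIOR))
    dwell: DwellParams = field(default_factory=DwellParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    #: Global multiplier on movement oscillation amplitudes (0 = static).
    dynamics_scale: float = 1.0
    #: Optional explicit priors overriding the age trajectories,
    #: e.g. ``{"prone": 1.0}``.
    posture_prior_override: dict | None = None
    movement_prior_override: dict | None = None
    carrying_prior_override: dict | None = None
    subject_id: str = "sim"

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.age_months < 0:
            raise ValueError(f"invalid age: {self.age_months}")
        for p, ok in (("packet_drop_p", self.noise.packet_drop_p),):
            if not 0.0 <= ok <= 1.0:
                raise ValueError(f"{p} must be in [0, 1]")
        if not self.posture_trajectories or not self.movement_trajectories:
            raise ValueError("empty taxonomy trajectories")


@dataclass
class StateSequence:
    """Per-second ground-truth labels on the three tracks (integer codes)."""

    posture: np.ndarray
    movement: np.ndarray
    carrying: np.ndarray

    @property
    def n_seconds(self) -> int:
        return int(self.posture.shape[0])


@dataclass
class SimRecording:
    """Synthetic 4-sensor recording with ground truth."""

    #: sensor id -> float array [n_packets, 7]: (t, ax, ay, az, gx, gy, gz)
    streams: dict[str, np.ndarray]
    ground_truth: StateSequence
    gyro_bias_true: dict[str, np.ndarray]
    metadata: dict


# --------------------------------------------------------------------------
# Priors
# --------------------------------------------------------------------------

def _curve(age: float, spec: dict) -> float:
    if spec["kind"] == "logistic":
        return spec["lo"] + (spec["hi"] - spec["lo"]) / (
            1.0 + math.exp(-spec["slope"] * (age - spec["mid"])))
    if spec["kind"] == "bell":
        z = (age - spec["mid"]) / spec["width"]
        return spec["base"] + spec["amp"] * math.exp(-0.5 * z * z)
    raise ValueError(f"unknown trajectory kind {spec['kind']!r}")


def _prior_from_override(override: dict, classes) -> np.ndarray:
    p = np.zeros(len(classes))
    for name, w in override.items():
        if name not in classes:
            raise ValueError(f"unknown class {name!r}")
        p[classes.index(name)] = w
    if p.sum() <= 0:
        raise ValueError("override prior must have positive mass")
    return p / p.sum()


def posture_prior(cfg: SimConfig) -> np.ndarray:
    """Normalized 7-class posture occupancy prior at the configured age."""
    if cfg.posture_prior_override is not None:
        return _prior_from_override(cfg.posture_prior_override, list(POSTURES))
    w = np.array([_curve(cfg.age_months, cfg.posture_trajectories[c]) for c in POSTURES])
    return w / w.sum()


def movement_conditional_prior(cfg: SimConfig) -> np.ndarray:
    """[7, 9] matrix: movement prior conditional on posture (masked by
    posture/movement compatibility, rows normalized)."""
    if cfg.movement_prior_override is not None:
        base = _prior_from_override(cfg.movement_prior_override, list(MOVEMENTS))
    else:
        base = np.array(
            [_curve(cfg.age_months, cfg.movement_trajectories[c]) for c in MOVEMENTS])
    cond = np.zeros((len(POSTURES), len(MOVEMENTS)))
    for i, post in enumerate(POSTURES):
        allowed = ALLOWED_MOVEMENTS[post]
        mask = np.array([m in allowed for m in MOVEMENTS], float)
        row = base * mask
        if row.sum() <= 0:  # override incompatible with this posture
            row = mask
        cond[i] = row / row.sum()
    return cond


def carrying_prior(cfg: SimConfig) -> np.ndarray:
    if cfg.carrying_prior_override is not None:
        return _prior_from_override(cfg.carrying_prior_override, list(CARRYING))
    p = np.array([cfg.carrying_prior[c] for c in CARRYING])
    return p / p.sum()


# --------------------------------------------------------------------------
# State-sequence generation
# --------------------------------------------------------------------------

def _draw_dwell(rng: np.random.Generator, mean_s: float) -> int:
    # Geometric dwell with the configured mean (support {1, 2, ...}).
    return int(rng.geometric(min(1.0, 1.0 / max(mean_s, 1.0))))


def _schedule(n: int, prior: np.ndarray, mean_dwell: float,
              rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov sequence whose occupancy tracks ``prior``.

    Successive segment states are drawn proportionally to the current
    occupancy deficit (target minus realized time share), which makes the
    empirical occupancy converge to the prior at rate ~dwell/duration
    rather than the 1/sqrt(n) of independent draws.
    """
    out = np.empty(n, dtype=np.int64)
    spent = np.zeros(len(prior))
    t = 0
    while t < n:
        deficit = prior * (t + mean_dwell) - spent
        w = np.clip(deficit, 0.0, None)
        if w.sum() <= 0:
            w = prior.copy()
        state = int(rng.choice(len(prior), p=w / w.sum()))
        dwell = min(_draw_dwell(rng, mean_dwell), n - t)
        out[t:t + dwell] = state
        spent[state] += dwell
        t += dwell
    return out


def simulate_state_sequence(cfg: SimConfig) -> StateSequence:
    """Generate a per-second ground-truth state sequence.

    The posture track follows the age-dependent posture prior; the
    movement track follows the age-dependent movement prior conditioned on
    (and masked by) the current posture; carrying is independent.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s))

    p_post = posture_prior(cfg)
    cond = movement_conditional_prior(cfg)
    p_carry = carrying_prior(cfg)

    posture = _schedule(n, p_post, cfg.dwell.posture_s, rng)

    # Movement: deficit scheduling per posture so each posture-conditional
    # occupancy converges to its configured conditional prior.
    movement = np.empty(n, dtype=np.int64)
    spent = np.zeros_like(cond)
    elapsed = np.zeros(len(POSTURES))
    # iterate over posture segments
    bounds = np.flatnonzero(np.diff(posture)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [n]))
    for s, e in zip(starts, ends):
        post = int(posture[s])
        prior = cond[post]
        t = s
        while t < e:
            deficit = prior * (elapsed[post] + cfg.dwell.movement_s) - spent[post]
            w = np.clip(deficit, 0.0, None)
            if w.sum() <= 0:
                w = prior.copy()
            state = int(rng.choice(len(prior), p=w / w.sum()))
            dwell = min(_draw_dwell(rng, cfg.dwell.movement_s), e - t)
            movement[t:t + dwell] = state
            spent[post, state] += dwell
            elapsed[post] += dwell
            t += dwell

    carrying = _schedule(n, p_carry, cfg.dwell.carrying_s, rng)
    return StateSequence(posture=posture, movement=movement, carrying=carrying)


# --------------------------------------------------------------------------
# IMU synthesis
# --------------------------------------------------------------------------

def synthesize_imu(seq: StateSequence, cfg: SimConfig) -> SimRecording:
    """Render a state sequence into 4 timestamped 6-channel IMU streams.

    Accelerometers read the posture's per-sensor gravity vector plus a
    movement oscillation whose SD follows the movement class's amplitude
    tier; gyroscopes read a per-sensor constant bias plus the matching
    angular-velocity oscillation. Active/passive carrying adds a
    common-mode adult-gait sinusoid to all sensors. Packet timestamps get
    Gaussian jitter; packets are dropped i.i.d. with the configured
    probability.
    """
    if seq.n_seconds == 0:
        raise ValueError("empty state sequence")
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51]))
    n_sec = seq.n_seconds
    rate = SAMPLE_RATE
    m = int(round(n_sec * rate))
    base_t = np.arange(m) / rate
    sec_idx = np.minimum((np.arange(m) // int(rate)).astype(int), n_sec - 1)

    # per-segment movement amplitudes (overlapping lognormal tiers)
    amp_acc = np.zeros(n_sec)
    amp_gyr = np.zeros(n_sec)
    bounds = np.flatnonzero(np.diff(seq.movement)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [n_sec]))
    for s, e in zip(starts, ends):
        mv = MOVEMENTS[int(seq.movement[s])]
        a0, g0 = MOVEMENT_AMPLITUDE[mv]
        f = math.exp(rng.normal(0.0, AMPLITUDE_SIGMA)) if a0 > 0 else 0.0
        amp_acc[s:e] = a0 * f * cfg.dynamics_scale
        amp_gyr[s:e] = g0 * f * cfg.dynamics_scale

    # carrying common-mode signal (same across sensors)
    carry_acc = np.zeros(m)
    carry_names = [CARRYING[int(c)] for c in seq.carrying]
    for cls, (freq, amp) in CARRY_SIGNATURE.items():
        mask_sec = np.array([c == cls for c in carry_names])
        if mask_sec.any():
            phase = rng.uniform(0, 2 * np.pi)
            carry_acc += (mask_sec[sec_idx] * amp * cfg.dynamics_scale
                          * np.sin(2 * np.pi * freq * base_t + phase))

    grav = np.stack([
        np.stack([GRAVITY_ORIENTATION[POSTURES[p]][s] for p in range(len(POSTURES))])
        for s in SENSORS])  # [sensor, posture, 3]

    streams: dict[str, np.ndarray] = {}
    bias_true: dict[str, np.ndarray] = {}
    for si, sensor in enumerate(SENSORS):
        bias = rng.uniform(-cfg.noise.gyro_bias_range, cfg.noise.gyro_bias_range, 3)
        bias_true[sensor] = bias

        acc = GRAVITY * grav[si][seq.posture[sec_idx]]  # [m, 3]
        acc = acc + amp_acc[sec_idx, None] * rng.standard_normal((m, 3))
        acc = acc + carry_acc[:, None]
        acc = acc + cfg.noise.accel_noise_sd * rng.standard_normal((m, 3))

        gyr = bias[None, :] + amp_gyr[sec_idx, None] * rng.standard_normal((m, 3))
        gyr = gyr + cfg.noise.gyro_noise_sd * rng.standard_normal((m, 3))

        t = base_t + cfg.noise.packet_jitter_sd * rng.standard_normal(m)
        t = np.sort(t)
        # enforce strictly increasing timestamps
        t = np.maximum.accumulate(t + 1e-9 * np.arange(m)) if m else t

        keep = rng.random(m) >= cfg.noise.packet_drop_p
        packets = np.column_stack([t, acc, gyr])[keep]
        streams[sensor] = packets

    meta = {
        "subject_id": cfg.subject_id,
        "age_months": float(cfg.age_months),
        "duration_s": float(cfg.duration_s),
        "seed": int(cfg.seed),
    }
    return SimRecording(streams=streams, ground_truth=seq,
                        gyro_bias_true=bias_true, metadata=meta)


# --------------------------------------------------------------------------
# Rater simulation
# --------------------------------------------------------------------------

def default_confusions(posture_acc: float = 0.99, movement_acc: float = 0.87,
                       carrying_acc: float = 0.98) -> dict[str, np.ndarray]:
    """Row-stochastic per-track confusion matrices: ``acc`` on the
    diagonal, remaining mass uniform over the other classes.

    The defaults, combined with the 0.5-s boundary jitter, reproduce the
    characteristic inter-rater agreement structure of second-level video
    annotation: near-perfect agreement on posture (Fleiss' kappa ~0.95)
    and markedly lower agreement on movement quality (~0.6)."""
    out = {}
    for track, acc in (("posture", posture_acc), ("movement", movement_acc),
                       ("carrying", carrying_acc)):
        k = len({"posture": POSTURES, "movement": MOVEMENTS,
                 "carrying": CARRYING}[track])
        cm = np.full((k, k), (1.0 - acc) / (k - 1))
        np.fill_diagonal(cm, acc)
        out[track] = cm
    return out


def _jitter_boundaries(labels: np.ndarray, jitter_s: float,
                       rng: np.random.Generator) -> np.ndarray:
    if jitter_s <= 0:
        return labels.copy()
    n = len(labels)
    bounds = np.flatnonzero(np.diff(labels)) + 1
    if len(bounds) == 0:
        return labels.copy()
    shifted = np.clip(np.round(bounds + rng.normal(0, jitter_s, len(bounds))), 1, n - 1)
    shifted = np.maximum.accumulate(shifted).astype(int)
    states = labels[np.concatenate(([0], bounds))]
    out = np.empty(n, dtype=labels.dtype)
    starts = np.concatenate(([0], shifted))
    ends = np.concatenate((shifted, [n]))
    for st, (s, e) in zip(states, zip(starts, ends)):
        out[s:e] = st
    return out


def _apply_confusion(labels: np.ndarray, cm: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(cm, axis=1)
    u = rng.random(len(labels))
    out = np.empty_like(labels)
    for c in range(cm.shape[0]):
        mask = labels == c
        if mask.any():
            out[mask] = np.searchsorted(cdf[c], u[mask], side="right")
    return np.minimum(out, cm.shape[0] - 1)


def simulate_raters(seq: StateSequence, confusion: dict[str, np.ndarray] | None = None,
                    boundary_jitter_s: float = 0.5, n_raters: int = 3,
                    seed: int = 0):
    """Simulate independent human annotators.

    Each rater observes the ground truth through (1) Gaussian jitter of
    segment boundaries and (2) per-second confusion sampling — the two
    dominant disagreement modes in video annotation.
    """
    from .annotations import AnnotationSet

    if n_raters < 2:
        raise ValueError("n_raters must be >= 2 (agreement undefined otherwise)")
    confusion = confusion if confusion is not None else default_confusions()
    for track, cm in confusion.items():
        cm = np.asarray(cm, float)
        if not np.allclose(cm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError(f"confusion rows for {track!r} must normalize to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA7]))

    tracks = {"posture": seq.posture, "movement": seq.movement,
              "carrying": seq.carrying}
    data = {t: np.empty((n_raters, seq.n_seconds), dtype=np.int64) for t in tracks}
    for r in range(n_raters):
        for track, truth in tracks.items():
            lab = _jitter_boundaries(truth, boundary_jitter_s, rng)
            cm = np.asarray(confusion[track], float)
            data[track][r] = _apply_confusion(lab, cm, rng)
    raters = [f"rater_{i + 1}" for i in range(n_raters)]
    return AnnotationSet(raters=raters, data=data)


# --------------------------------------------------------------------------
# Cohort generation (recording-level motor feature vectors)
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """Recording-level cohort: ages, subjects, and motor feature vectors."""

    subjects: list[str]
    ages: np.ndarray
    X: np.ndarray
    feature_names: list[str]


def mean_feature_vector(cfg: SimConfig) -> np.ndarray:
    """Expected motor feature vector at the configured age: fused posture
    occupancies followed by fused posture-conditional movement blocks."""
    p_post = posture_prior(cfg)
    cond = movement_conditional_prior(cfg)

    fused_post = np.zeros(len(FUSED_POSTURES))
    for i, post in enumerate(POSTURES):
        fused_post[FUSED_POSTURES.index(POSTURE_FUSE_MAP[post])] += p_post[i]

    blocks = [fused_post / fused_post.sum()]
    for fp in FUSED_POSTURES:
        members = [i for i, p in enumerate(POSTURES) if POSTURE_FUSE_MAP[p] == fp]
        w = p_post[members]
        w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1.0 / len(members))
        row9 = (w[:, None] * cond[members]).sum(axis=0)
        fused = np.zeros(len(FUSED_MOVEMENTS))
        for j, mv in enumerate(MOVEMENTS):
            fused[FUSED_MOVEMENTS.index(MOVEMENT_FUSE_MAP[mv])] += row9[j]
        blocks.append(fused / fused.sum())
    return np.concatenate(blocks)


def feature_names() -> list[str]:
    names = [f"posture:{p}" for p in FUSED_POSTURES]
    for fp in FUSED_POSTURES:
        names += [f"movement|{fp}:{m}" for m in FUSED_MOVEMENTS]
    return names


def generate_age_cohort(n_recordings: int, age_range=(4.0, 16.0),
                        trajectory_params: dict | None = None,
                        concentration: float = 80.0, seed: int = 0) -> Cohort:
    """Draw a cohort of recording-level motor feature vectors.

    Each recording's age is uniform on ``age_range``; each simplex block
    of its feature vector is a Dirichlet perturbation of the age-dependent
    mean trajectory with the given concentration (``inf`` = noiseless).
    """
    if n_recordings < 2:
        raise ValueError("n_recordings must be >= 2")
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    lo, hi = age_range
    ages = np.sort(rng.uniform(lo, hi, n_recordings))

    n_post = len(FUSED_POSTURES)
    n_mov = len(FUSED_MOVEMENTS)
    X = np.empty((n_recordings, n_post + n_post * n_mov))
    for i, age in enumerate(ages):
        cfg = SimConfig(age_months=float(age))
        if trajectory_params:
            cfg.posture_trajectories = trajectory_params.get(
                "posture", cfg.posture_trajectories)
            cfg.movement_trajectories = trajectory_params.get(
                "movement", cfg.movement_trajectories)
        mean = mean_feature_vector(cfg)
        if np.isinf(concentration):
            X[i] = mean
            continue
        vec = np.empty_like(mean)
        ofs = 0
        for blk in [n_post] + [n_mov] * n_post:
            alpha = concentration * mean[ofs:ofs + blk] + 1e-3
            vec[ofs:ofs + blk] = rng.dirichlet(alpha)
            ofs += blk
        X[i] = vec
    subjects = [f"subj_{i:03d}" for i in range(n_recordings)]
    return Cohort(subjects=subjects, ages=ages, X=X, feature_names=feature_names())
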