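"""Synthetic two-wrist accelerometer cohort generator.

Emulates a stroke-vs-control study in which participants wear one
tri-axial accelerometer per wrist while performing scripted activities of
daily living (unimanual, bimanual, passive, task-free).  Goal-directed
movements (GDM) are modelled as trains of minimum-jerk reaches whose
kinematics degrade with upper-limb impairment: reach amplitude shrinks,
while tremor and corrective sub-movements add direction reversals.  Passive
activity is gait-like arm-swing oscillation; task-free periods are
low-amplitude coloured noise.  A 9.81 m/s^2 gravity vector with slow
orientation drift rides on every sample, so the downstream 0.1 Hz
high-pass has a realistic DC component to remove.

All randomness flows through :class:`numpy.random.Generator` seeded from the
caller, making every session reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _signal

Side = Literal["left", "right"]
TaskType = Literal["unimanual", "bimanual", "passive", "task_free"]

#: manual labelling granularity, seconds
LABEL_GRANULARITY_S = 2.5

# Impairment -> FMA linear map, calibrated so a large stroke group with
# impairment ~ U(0.3, 0.9) has FMA mean ~37 and SD ~8-9.
_FMA_MAX = 66
_FMA_SLOPE = 48.0
_FMA_NOISE_SD = 4.0
_FMA_FLOOR = 10

_IMPAIRMENT_LOW = 0.3
_IMPAIRMENT_HIGH = 0.9


@dataclass(frozen=True)
class SubjectSpec:
    """One participant: identity, group, impairment level and limb roles.

    ``impairment`` is a latent severity in [0, 1] (0 = unimpaired) that
    drives the kinematic degradation in the simulator; ``fma`` is the
    Fugl-Meyer upper-extremity score (max 66) derived from it.  For
    controls the non-dominant arm plays the role of the affected side
    during unimanual tasks.
    """

    subject_id: str
    group: Literal["stroke", "control"]
    impairment: float
    fma: int
    affected_side: Side

    def __post_init__(self) -> None:
        if self.group == "control" and self.impairment != 0:
            raise ValueError("controls must have impairment 0")
        if self.group == "stroke" and not self.impairment > 0:
            raise ValueError("stroke subjects must have impairment > 0")
        if not _FMA_FLOOR <= self.fma <= _FMA_MAX:
            raise ValueError(f"fma must lie in [{_FMA_FLOOR}, {_FMA_MAX}]")


@dataclass(frozen=True)
class TaskSegment:
    task_type: TaskType
    duration_s: float
    active_side: Literal["left", "right", "both", "none"]

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.task_type == "unimanual" and self.active_side not in ("left", "right"):
            raise ValueError("unimanual segments name exactly one active side")
        if self.task_type == "bimanual" and self.active_side != "both":
            raise ValueError("bimanual segments are active on both sides")
        if self.task_type in ("passive", "task_free") and self.active_side != "none":
            raise ValueError(f"{self.task_type} segments have no active side")
        if round(self.duration_s / LABEL_GRANULARITY_S) * LABEL_GRANULARITY_S != self.duration_s:
            raise ValueError(
                f"segment duration must be a multiple of {LABEL_GRANULARITY_S} s"
            )


@dataclass(frozen=True)
class TaskScript:
    """Ordered activity segments for one recording, both wrists."""

    segments: tuple[TaskSegment, ...]

    @property
    def total_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))


@dataclass
class Session:
    """One wrist's raw recording: tri-axial acceleration plus sample labels.

    ``task_type`` follows the labelling convention of the study design: the
    passive side of a unimanual segment is recorded as ``task_free``.
    ``active`` marks samples where *this* wrist performs a goal-directed
    movement.
    """

    subject_id: str
    side: Side
    fs: float
    acc: np.ndarray  # (n, 3) m/s^2
    task_type: np.ndarray  # (n,) of str
    active: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if len(self.task_type) != len(self.acc) or len(self.active) != len(self.acc):
            raise ValueError("sample labels must match acc length")
        if not self.fs > 24:
            raise ValueError("sampling rate must exceed 24 Hz")


def make_cohort(n_stroke: int, n_control: int, seed: int) -> list[SubjectSpec]:
    """Draw a cohort of stroke and control subject specifications.

    Stroke impairment is Uniform(0.3, 0.9); FMA is a noisy linear map of
    impairment (slope 48 from a ceiling of 66, Gaussian noise SD 4) clipped
    to [10, 66], calibrated so that a large stroke group has FMA mean ~37
    and SD ~8-9.  Controls have impairment 0 and FMA 66.  Deterministic
    given ``seed``.
    """
    if n_stroke < 0 or n_control < 0:
        raise ValueError("subject counts must be non-negative")
    rng = np.random.default_rng(seed)
    cohort: list[SubjectSpec] = []
    for i in range(n_stroke):
        impairment = float(rng.uniform(_IMPAIRMENT_LOW, _IMPAIRMENT_HIGH))
        fma = int(np.clip(
            round(_FMA_MAX - _FMA_SLOPE * impairment + rng.normal(0, _FMA_NOISE_SD)),
            _FMA_FLOOR, _FMA_MAX,
        ))
        side: Side = "left" if rng.random() < 0.5 else "right"
        cohort.append(SubjectSpec(f"S{i + 1:02d}", "stroke", impairment, fma, side))
    for i in range(n_control):
        side = "left" if rng.random() < 0.5 else "right"
        cohort.append(SubjectSpec(f"C{i + 1:02d}", "control", 0.0, _FMA_MAX, side))
    return cohort


def minimum_jerk_reach(
    distance: float, duration: float, fs: float, direction: np.ndarray
) -> np.ndarray:
    """Tri-axial acceleration of one minimum-jerk point-to-point reach.

    The along-movement position follows the classic fifth-order polynomial
    s(tau) = d * (10 tau^3 - 15 tau^4 + 6 tau^5); acceleration is its
    analytic second derivative projected on a caller-supplied unit
    ``direction``.  Acceleration is zero at both endpoints and its time
    integral over the reach vanishes (the hand starts and ends at rest).

    Returns an array of shape (round(duration*fs), 3) in m/s^2.
    """
    if distance <= 0 or duration <= 0:
        raise ValueError("distance and duration must be positive")
    direction = np.asarray(direction, dtype=float)
    if direction.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    n = int(round(duration * fs))
    tau = np.arange(n) / (duration * fs)  # tau in [0, 1)
    # s''(tau) / duration^2, from s(tau) = d(10 tau^3 - 15 tau^4 + 6 tau^5)
    a = distance * (60 * tau - 180 * tau**2 + 120 * tau**3) / duration**2
    return a[:, None] * direction[None, :]


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _gdm_segment(n: int, fs: float, impairment: float, rng: np.random.Generator) -> np.ndarray:
    """Train of reaches with impairment-graded tremor and corrections."""
    acc = np.zeros((n, 3))
    amp_scale = 1.0 - 0.5 * impairment
    t = 0
    while t < n:
        duration = rng.uniform(0.5, 1.5)
        distance = rng.uniform(0.2, 0.6) * amp_scale
        reach = minimum_jerk_reach(distance, duration, fs, _unit_vector(rng))
        m = min(len(reach), n - t)
        acc[t:t + m] += reach[:m]
        # corrective sub-movements: small slow adjustments, more when impaired
        for _ in range(rng.poisson(3.0 * impairment)):
            cd = rng.uniform(0.3, 0.5)
            blip = minimum_jerk_reach(rng.uniform(0.01, 0.03), cd, fs, _unit_vector(rng))
            off = t + int(rng.uniform(0.3, 0.9) * m)
            k = min(len(blip), n - off)
            if k > 0:
                acc[off:off + k] += blip[:k]
        t += m + int(rng.uniform(0.1, 0.4) * fs)  # inter-reach hold
    if impairment > 0:
        # 4-6 Hz action tremor graded with impairment; mostly riding on the
        # movement envelope (action tremor), with a small postural floor
        f = rng.uniform(4.0, 6.0)
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n) / fs
        env = np.abs(acc).max(axis=1)
        kernel = np.ones(int(fs // 2)) / (fs // 2)
        env = np.convolve(env, kernel, mode="same")
        amp = impairment * (0.1 + 0.5 * np.minimum(env, 1.5))
        tremor = amp * np.sin(2 * np.pi * f * tt + phase)
        acc += tremor[:, None] * _unit_vector(rng)[None, :]
    return acc


def _passive_segment(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gait-like arm swing: a 1.8-2.2 Hz oscillation along one direction."""
    f = rng.uniform(1.8, 2.2)
    amp = rng.uniform(1.0, 2.0)
    phase = rng.uniform(0, 2 * np.pi)
    tt = np.arange(n) / fs
    swing = amp * np.sin(2 * np.pi * f * tt + phase)
    return swing[:, None] * _unit_vector(rng)[None, :]


def _taskfree_segment(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Low-amplitude coloured noise (fidgeting, posture adjustments)."""
    white = rng.normal(0, 1.0, size=(max(n, 32), 3))
    sos = _signal.butter(2, 3.0, btype="low", fs=fs, output="sos")
    colored = _signal.sosfilt(sos, white, axis=0)[:n]
    rms = np.sqrt(np.mean(colored**2)) or 1.0
    return 0.15 * colored / rms


def _gravity(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Constant-magnitude 9.81 m/s^2 vector with slow orientation drift."""
    g0 = _unit_vector(rng)
    steps = rng.normal(0, 0.02 / fs, size=(n, 3))
    drift = np.cumsum(steps, axis=0)
    vec = g0[None, :] + drift
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return 9.81 * vec


def make_task_script(
    rng: np.random.Generator,
    affected_side: Side,
    total_s: float = 120.0,
    task_weights: dict[str, float] | None = None,
) -> TaskScript:
    """Random ADL-like script with segment boundaries on the 2.5 s grid.

    Every script contains at least two bimanual, two unimanual and one
    passive segment (the protocol scripts each motor task for every
    participant); the remaining time is filled with randomly drawn
    segments.  Unimanual segments are always performed with the affected
    (or, for controls, non-dominant) arm, matching the study protocol.
    """
    # task-free dominates recording time, as in real ADL monitoring
    weights = task_weights or {
        "task_free": 0.65, "bimanual": 0.1, "unimanual": 0.1, "passive": 0.15,
    }
    kinds = list(weights)
    p = np.array([weights[k] for k in kinds], dtype=float)
    p /= p.sum()
    remaining = round(total_s / LABEL_GRANULARITY_S)  # in 2.5 s units
    drawn: list[tuple[str, int]] = []
    for kind in ("bimanual", "bimanual", "unimanual", "unimanual", "passive"):
        units = min(int(rng.integers(2, 5)), remaining)  # 5-10 s
        if units > 0:
            drawn.append((kind, units))
            remaining -= units
    while remaining > 0:
        units = min(int(rng.integers(2, 9)), remaining)  # 5-20 s
        drawn.append((kinds[rng.choice(len(kinds), p=p)], units))
        remaining -= units
    order = rng.permutation(len(drawn))
    segments = []
    for k in order:
        kind, units = drawn[k]
        active = {"unimanual": affected_side, "bimanual": "both"}.get(kind, "none")
        segments.append(TaskSegment(kind, units * LABEL_GRANULARITY_S, active))
    return TaskScript(tuple(segments))


def simulate_session(
    subject: SubjectSpec,
    script: TaskScript,
    side: Side,
    fs_raw: float = 100.0,
    seed: int = 0,
) -> Session:
    """Simulate one wrist's raw accelerometer stream for a task script.

    The wrist is *active* during bimanual segments and during unimanual
    segments naming it; its signal there is a reach train shaped by the
    subject's impairment.  The passive wrist of a unimanual segment carries
    task-free-like signal and is *labelled* task-free, following the study's
    labelling convention.  Passive segments are arm-swing oscillation on
    both wrists; task-free segments are coloured noise.  Gravity (with slow
    orientation drift) and white sensor noise are added throughout.
    """
    if fs_raw < 50:
        raise ValueError("fs_raw must be at least 50 Hz")
    if not script.segments or script.total_s <= 0:
        raise ValueError("script must have positive total duration")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    task_labels: list[np.ndarray] = []
    active_labels: list[np.ndarray] = []
    for seg in script.segments:
        n = int(round(seg.duration_s * fs_raw))
        is_active = seg.task_type == "bimanual" or (
            seg.task_type == "unimanual" and seg.active_side == side
        )
        if is_active:
            sig = _gdm_segment(n, fs_raw, subject.impairment, rng)
            label = seg.task_type
        elif seg.task_type == "passive":
            sig = _passive_segment(n, fs_raw, rng)
            label = "passive"
        else:
            # task_free proper, or the passive side of a unimanual segment
            sig = _taskfree_segment(n, fs_raw, rng)
            label = "task_free"
        chunks.append(sig)
        task_labels.append(np.full(n, label, dtype=object))
        active_labels.append(np.full(n, is_active, dtype=bool))
    acc = np.concatenate(chunks)
    n_total = len(acc)
    acc += _gravity(n_total, fs_raw, rng)
    acc += rng.normal(0, 0.05, size=acc.shape)  # sensor noise
    return Session(
        subject_id=subject.subject_id,
        side=side,
        fs=fs_raw,
        acc=acc,
        task_type=np.concatenate(task_labels),
        active=np.concatenate(active_labels),
    )


def simulate_cohort(
    subjects: Sequence[SubjectSpec],
    seed: int,
    total_s: float = 120.0,
    fs_raw: float = 100.0,
) -> dict[tuple[str, Side], Session]:
    """Simulate both wrists for every subject; one shared script per subject.

    Per-session seeds are derived with :class:`numpy.random.SeedSequence`
    so any (subject, side) stream is reproducible independently of cohort
    size or ordering.
    """
    sessions: dict[tuple[str, Side], Session] = {}
    for i, subject in enumerate(subjects):
        script_rng = np.random.default_rng(np.random.SeedSequence([seed, i, 2]))
        script = make_task_script(script_rng, subject.affected_side, total_s=total_s)
        for j, side in enumerate(("left", "right")):
            child = np.random.SeedSequence([seed, i, j])
            session_seed = int(child.generate_state(1)[0] % (2**31))
            sessions[(subject.subject_id, side)] = simulate_session(
                subject, script, side, fs_raw=fs_raw, seed=session_seed
            )
    return sessions
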