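"""Deterministic task geometry, physics, scheduling, calibration and reward.

The visuomotor task: a sustained finger press launches a ball cursor that
decelerates to a stop; the participant aims at a close or far target whose
distance corresponds to 35% (low effort) or 65% (high effort) of their
maximum voluntary force.  These routines are shared by the trial simulator
and the analysis pipeline so that simulated and analysed geometry can never
drift apart.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

EFFORT_LEVELS = ("low", "high")
REWARD_LEVELS = ("no", "yes")
CONDITIONS = tuple((e, r) for e in EFFORT_LEVELS for r in REWARD_LEVELS)

FORCE_SAMPLE_HZ = 60


@dataclass(frozen=True)
class TaskConfig:
    """Geometry, physics and schedule constants of the visuomotor task.

    Lengths are continuous pixels on a 0-based x axis; forces are fractions
    of the participant's maximum voluntary force.
    """

    screen_width_px: float = 1280.0
    start_x_px: float = 128.0
    close_target_x_px: float = 512.0
    far_target_x_px: float = 896.0
    ball_radius_px: float = 32.0
    target_radius_px: float = 38.0
    #: initial speed, as fraction of screen width per second, produced by
    #: pressing at one quarter of maximum force
    velocity_per_quarter_maxforce: float = 0.30
    #: extra scaling of applied force before the force->velocity conversion
    force_scale: float = 0.5
    effort_fractions: dict = field(default_factory=lambda: {"low": 0.35, "high": 0.65})
    reward_max: float = 1.0
    #: |performance error| (as fraction of screen width) at which reward hits 0
    reward_zero_distance: dict = field(default_factory=lambda: {"low": 0.15, "high": 0.30})
    n_blocks: int = 40
    trials_per_block: int = 27
    basic_per_block: int = 19
    estimation_per_block: int = 8
    blocks_per_condition: int = 10

    def __post_init__(self) -> None:
        if self.basic_per_block + self.estimation_per_block != self.trials_per_block:
            raise ValueError("basic + estimation trials must equal trials_per_block")
        if self.n_blocks != 4 * self.blocks_per_condition:
            raise ValueError("n_blocks must equal 4 * blocks_per_condition")
        if not (self.start_x_px < self.close_target_x_px < self.far_target_x_px
                < self.screen_width_px):
            raise ValueError("require start < close target < far target < screen width")

    def target_x(self, effort: str) -> float:
        return self.close_target_x_px if effort == "low" else self.far_target_x_px

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "TaskConfig":
        text = open(path).read()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


@dataclass
class Trial:
    """One trial: condition, response and the derived error measures.

    ``force_error`` is signed % of maximum force; ``performance_error`` is
    x_true − x_target in px; ``estimation_error`` (estimation trials only)
    is x_estimate − x_true in px.
    """

    participant_id: str
    block: int
    trial_in_block: int
    effort: str
    reward: str
    trial_type: str  # "basic" | "estimation"
    force_response: float | None = None
    force_error: float | None = None
    x_true: float | None = None
    x_target: float | None = None
    performance_error: float | None = None
    x_estimate: float | None = None
    estimation_error: float | None = None


@dataclass(frozen=True)
class ForceTrace:
    """Force-sensor recording at 60 Hz."""

    samples: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        n_expected = round(FORCE_SAMPLE_HZ * self.duration_s)
        if len(self.samples) != n_expected:
            raise ValueError(
                f"trace has {len(self.samples)} samples, expected {n_expected} "
                f"for {self.duration_s} s at {FORCE_SAMPLE_HZ} Hz")
        if np.any(np.asarray(self.samples) < 0):
            raise ValueError("force samples must be non-negative")


# ---------------------------------------------------------------------------
# physics


def _initial_velocity(force_fraction: float, config: TaskConfig) -> float:
    """Initial ball speed in px/s for a force response (fraction of max)."""
    return (config.force_scale * force_fraction / 0.25) \
        * config.velocity_per_quarter_maxforce * config.screen_width_px


def deceleration(effort: str, config: TaskConfig) -> float:
    """Per-effort deceleration (px/s^2) calibrated so the nominal effort
    force lands exactly on the corresponding target center."""
    v_nom = _initial_velocity(config.effort_fractions[effort], config)
    distance = config.target_x(effort) - config.start_x_px
    return v_nom ** 2 / (2.0 * distance)


def force_to_position(force_fraction, effort: str, config: TaskConfig | None = None):
    """Map a force response (fraction of max force) to the ball's final
    x position in px.  Strictly increasing and invertible before clipping;
    positions are clipped to [start, screen width]."""
    config = config or TaskConfig()
    force_fraction = np.asarray(force_fraction, dtype=float)
    if np.any(force_fraction < 0):
        raise ValueError("force_fraction must be non-negative")
    v = _initial_velocity(force_fraction, config)
    pos = config.start_x_px + v ** 2 / (2.0 * deceleration(effort, config))
    return np.clip(pos, config.start_x_px, config.screen_width_px)


def position_to_force(x: float, effort: str, config: TaskConfig | None = None):
    """Inverse of :func:`force_to_position` (within the unclipped range)."""
    config = config or TaskConfig()
    x = np.asarray(x, dtype=float)
    v = np.sqrt(np.maximum(2.0 * deceleration(effort, config) * (x - config.start_x_px), 0.0))
    return v / (_initial_velocity(1.0, config))


# ---------------------------------------------------------------------------
# force-trace processing


def extract_force_response(trace: ForceTrace, max_force: float) -> float:
    """Mean force in the [2.0 s, 2.5 s) window as a fraction of max force."""
    if trace.duration_s < 2.5:
        raise ValueError("trace must be at least 2.5 s long")
    lo = int(round(2.0 * FORCE_SAMPLE_HZ))
    hi = int(round(2.5 * FORCE_SAMPLE_HZ))
    return float(np.mean(trace.samples[lo:hi])) / max_force


def calibrate_max_force(traces: list[ForceTrace], window_s: float = 5.0) -> float:
    """Maximum voluntary force from three 10-s sustained presses.

    For each trace the 5-s window with the lowest sample variance is found
    and its mean taken; the maximum of the three per-trace means is the
    participant's maximum force.
    """
    if len(traces) != 3:
        raise ValueError("calibration requires exactly three traces")
    per_trace = []
    for trace in traces:
        if trace.duration_s < 10.0:
            raise ValueError("calibration traces must be at least 10 s long")
        samples = np.asarray(trace.samples, dtype=float)
        w = int(round(window_s * FORCE_SAMPLE_HZ))
        n = len(samples)
        # cumulative-sum sliding variance over all offsets
        c1 = np.concatenate([[0.0], np.cumsum(samples)])
        c2 = np.concatenate([[0.0], np.cumsum(samples ** 2)])
        means = (c1[w:] - c1[:n - w + 1]) / w
        variances = (c2[w:] - c2[:n - w + 1]) / w - means ** 2
        per_trace.append(means[int(np.argmin(variances))])
    return float(max(per_trace))


# ---------------------------------------------------------------------------
# reward


def reward_points(performance_error, effort: str, config: TaskConfig | None = None):
    """Reward in £: maximum at zero error, decreasing linearly to £0 at the
    per-effort zero-reward distance, never negative."""
    config = config or TaskConfig()
    err = np.abs(np.asarray(performance_error, dtype=float))
    zero_at = config.reward_zero_distance[effort] * config.screen_width_px
    return np.maximum(config.reward_max * (1.0 - err / zero_at), 0.0)


# ---------------------------------------------------------------------------
# scheduling


def _block_trial_types(config: TaskConfig, rng: np.random.Generator,
                       max_tries: int = 10_000) -> list[str]:
    """One block's trial-type order: first three basic, no two consecutive
    estimation trials, by rejection sampling."""
    n, k = config.trials_per_block, config.estimation_per_block
    if k == 0:
        return ["basic"] * n
    # feasibility: estimation trials occupy non-adjacent slots after trial 3
    free = n - 3
    if free <= 0 or k > (free + 1) // 2:
        raise ValueError("estimation_per_block too large for the scheduling constraints")
    types = np.array(["basic"] * n, dtype=object)
    for _ in range(max_tries):
        slots = rng.choice(np.arange(3, n), size=k, replace=False)
        slots.sort()
        if np.all(np.diff(slots) > 1):
            types[:] = "basic"
            types[slots] = "estimation"
            return list(types)
    raise ValueError("could not satisfy scheduling constraints")


def generate_schedule(config: TaskConfig | None = None, seed: int = 0,
                      participant_id: str = "p01") -> list[Trial]:
    """Pseudorandom trial schedule for one participant.

    Blocks: a seeded shuffle of ``blocks_per_condition`` copies of each of
    the four effort×reward cells.  Within each block, trial types satisfy
    the task's constraints (trials 1–3 basic, no adjacent estimation
    trials).  Reproducible for a fixed seed.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    conditions = [c for c in CONDITIONS for _ in range(config.blocks_per_condition)]
    order = rng.permutation(len(conditions))
    trials: list[Trial] = []
    for block_idx, cond_idx in enumerate(order, start=1):
        effort, reward = conditions[cond_idx]
        for trial_idx, ttype in enumerate(_block_trial_types(config, rng), start=1):
            trials.append(Trial(
                participant_id=participant_id, block=block_idx,
                trial_in_block=trial_idx, effort=effort, reward=reward,
                trial_type=ttype, x_target=config.target_x(effort)))
    return trials


def iter_blocks(trials: list[Trial]) -> Iterator[list[Trial]]:
    block: list[Trial] = []
    for t in trials:
        if block and t.block != block[-1].block:
            yield block
            block = []
        block.append(t)
    if block:
        yield block
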