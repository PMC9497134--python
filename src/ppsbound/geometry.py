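"""Stimulus geometry of the looming visuo-tactile peripersonal-space task.

A virtual ball travels at constant velocity toward (looming) or away from
(receding) the participant's trunk. A vibrotactile tap is delivered at one of
five fixed delays from motion onset, so each delay maps deterministically to
the distance of the ball from the body at the moment of the tap. Distance
levels are labelled D1 (farthest) through D5 (nearest) by convention, so for
looming stimuli D1 corresponds to the *earliest* tap and for receding stimuli
to the *latest* one.

Coordinates: the body sits at 0 cm and distances grow positive away from the
trunk along the motion axis. Delays are seconds internally; milliseconds at
I/O boundaries (CSV columns, point-of-subjective-equality values).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError

__all__ = [
    "StimulusConfig",
    "DistanceLevel",
    "TrialBreakdown",
    "LOOMING",
    "RECEDING",
    "MULTISENSORY",
    "UNISENSORY",
    "CATCH",
    "delay_to_distance",
    "distance_to_delay",
    "distance_step",
    "pse_time_to_distance",
    "distance_levels",
    "build_session_schedule",
    "schedule_to_csv",
    "schedule_from_csv",
]

LOOMING = "looming"
RECEDING = "receding"

MULTISENSORY = "multisensory"
UNISENSORY = "unisensory_tactile"
CATCH = "catch_visual_only"

SCHEDULE_COLUMNS = [
    "trial_index",
    "block",
    "modality",
    "direction",
    "distance_label",
    "delay_ms",
    "distance_cm",
]


@dataclass(frozen=True)
class StimulusConfig:
    """Task constants: velocity, tap delays and trajectory endpoints.

    Parameters
    ----------
    velocity : float
        Ball speed in cm/s.
    tactile_delays : tuple of float
        Tap delays from motion onset, in seconds, strictly increasing.
    start_distance_looming : float
        Distance (cm) of the ball from the trunk at looming onset. The default
        199.5 cm reproduces the printed tap-distance range 37.12-167.03 cm at
        75 cm/s with the default delays.
    near_offset_receding : float
        Distance (cm) at receding onset; the default mirrors the looming
        construction so both directions tap at the same five distances.
    ball_diameter : float
        Stimulus diameter in cm (descriptive only).
    tactile_duration : float
        Vibrotactile tap duration in seconds (descriptive only).
    """

    velocity: float = 75.0
    tactile_delays: tuple[float, ...] = (0.433, 0.866, 1.299, 1.732, 2.165)
    start_distance_looming: float = 199.5
    near_offset_receding: float = 4.65
    ball_diameter: float = 6.5
    tactile_duration: float = 0.010

    def __post_init__(self) -> None:
        object.__setattr__(self, "tactile_delays", tuple(float(d) for d in self.tactile_delays))
        if self.velocity <= 0:
            raise ConfigurationError(f"velocity must be > 0, got {self.velocity}")
        delays = np.asarray(self.tactile_delays, dtype=float)
        if delays.size < 1 or np.any(delays <= 0):
            raise ConfigurationError("tactile delays must be positive")
        if np.any(np.diff(delays) <= 0):
            raise ConfigurationError(f"tactile delays must be strictly increasing, got {self.tactile_delays}")
        if self.velocity * delays.max() >= self.start_distance_looming:
            raise ConfigurationError(
                "ball reaches the body before the last tap: "
                f"velocity*max(delay) = {self.velocity * delays.max():.3f} cm "
                f">= start_distance_looming = {self.start_distance_looming} cm"
            )
        if self.near_offset_receding <= 0:
            raise ConfigurationError("near_offset_receding must be > 0")

    @property
    def delays_ms(self) -> np.ndarray:
        """Tap delays in milliseconds."""
        return np.asarray(self.tactile_delays, dtype=float) * 1000.0

    # -- config file I/O ----------------------------------------------------
    # Keys carry units so config files are self-describing.

    def to_dict(self) -> dict:
        return {
            "velocity_cm_s": self.velocity,
            "delays_ms": [d * 1000.0 for d in self.tactile_delays],
            "start_distance_looming_cm": self.start_distance_looming,
            "near_offset_receding_cm": self.near_offset_receding,
            "ball_diameter_cm": self.ball_diameter,
            "tactile_duration_ms": self.tactile_duration * 1000.0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusConfig":
        known = {
            "velocity_cm_s",
            "delays_ms",
            "start_distance_looming_cm",
            "near_offset_receding_cm",
            "ball_diameter_cm",
            "tactile_duration_ms",
        }
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown stimulus config keys: {sorted(unknown)}")
        defaults = cls()
        return cls(
            velocity=float(d.get("velocity_cm_s", defaults.velocity)),
            tactile_delays=tuple(
                float(x) / 1000.0 for x in d.get("delays_ms", defaults.delays_ms)
            ),
            start_distance_looming=float(
                d.get("start_distance_looming_cm", defaults.start_distance_looming)
            ),
            near_offset_receding=float(
                d.get("near_offset_receding_cm", defaults.near_offset_receding)
            ),
            ball_diameter=float(d.get("ball_diameter_cm", defaults.ball_diameter)),
            tactile_duration=float(d.get("tactile_duration_ms", defaults.tactile_duration * 1000.0))
            / 1000.0,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StimulusConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass(frozen=True)
class DistanceLevel:
    """One tap level: label (D1 farthest ... D5 nearest), delay (s), distance (cm)."""

    label: str
    delay: float
    distance: float


def delay_to_distance(delay: float, direction: str, cfg: StimulusConfig | None = None) -> float:
    """Distance (cm) of the ball from the trunk at tap time.

    Looming: ``start_distance_looming - velocity * delay``.
    Receding: ``near_offset_receding + velocity * delay``.
    A delay of 0 returns the position at motion onset.
    """
    cfg = cfg or StimulusConfig()
    if delay < 0:
        raise ConfigurationError(f"delay must be >= 0 s, got {delay}")
    if direction == LOOMING:
        distance = cfg.start_distance_looming - cfg.velocity * delay
    elif direction == RECEDING:
        distance = cfg.near_offset_receding + cfg.velocity * delay
    else:
        raise ConfigurationError(f"direction must be {LOOMING!r} or {RECEDING!r}, got {direction!r}")
    if distance <= 0:
        raise ConfigurationError(
            f"delay {delay} s puts the {direction} ball at non-positive distance {distance:.3f} cm"
        )
    return distance


def distance_to_delay(distance: float, direction: str, cfg: StimulusConfig | None = None) -> float:
    """Inverse of :func:`delay_to_distance` (seconds)."""
    cfg = cfg or StimulusConfig()
    if direction == LOOMING:
        return (cfg.start_distance_looming - distance) / cfg.velocity
    if direction == RECEDING:
        return (distance - cfg.near_offset_receding) / cfg.velocity
    raise ConfigurationError(f"direction must be {LOOMING!r} or {RECEDING!r}, got {direction!r}")


def distance_step(cfg: StimulusConfig | None = None, atol: float = 1e-9) -> float:
    """Spatial spacing (cm) between successive tap distances.

    Requires equally spaced delays; with defaults 75 cm/s x 0.433 s = 32.475 cm
    (32.5 cm at one-decimal rounding).
    """
    cfg = cfg or StimulusConfig()
    gaps = np.diff(cfg.tactile_delays)
    if len(gaps) == 0:
        raise ConfigurationError("need at least two delays to define a step")
    if np.any(np.abs(gaps - gaps[0]) > atol):
        bad = int(np.argmax(np.abs(gaps - gaps[0])))
        raise ConfigurationError(
            f"delays not equally spaced: gap {bad + 1} is {gaps[bad]:.6f} s vs {gaps[0]:.6f} s"
        )
    return cfg.velocity * float(gaps[0])


def pse_time_to_distance(pse_ms: float, cfg: StimulusConfig | None = None) -> float:
    """Convert a PSE on the tap-delay axis (ms) to a body-centred distance (cm).

    Larger output means the boundary sits farther from the body (an expansion
    of peripersonal space corresponds to a *decrease* of the PSE in ms).
    """
    cfg = cfg or StimulusConfig()
    max_ms = max(cfg.tactile_delays) * 1000.0
    if not 0 < pse_ms <= max_ms:
        raise ConfigurationError(f"PSE must lie in (0, {max_ms:.0f}] ms, got {pse_ms}")
    return cfg.start_distance_looming - cfg.velocity * pse_ms / 1000.0


def distance_levels(cfg: StimulusConfig | None = None, direction: str = LOOMING) -> list[DistanceLevel]:
    """The D1..D5 levels for one direction, D1 farthest from the body."""
    cfg = cfg or StimulusConfig()
    levels = [
        DistanceLevel(label="", delay=d, distance=delay_to_distance(d, direction, cfg))
        for d in cfg.tactile_delays
    ]
    by_distance = sorted(levels, key=lambda lv: -lv.distance)
    return [dataclasses.replace(lv, label=f"D{i + 1}") for i, lv in enumerate(by_distance)]


@dataclass(frozen=True)
class TrialBreakdown:
    """Composition of one session.

    Defaults give 16 repetitions x 5 distances x {looming, receding} = 160
    multisensory trials, 30 unisensory tactile trials and 30 visual-only catch
    trials: 220 in total, split evenly across two blocks.
    """

    multisensory_reps: int = 16
    n_unisensory: int = 30
    n_catch: int = 30
    n_blocks: int = 2
    total_trials: int = 220

    def validate(self, n_levels: int) -> None:
        n_ms = self.multisensory_reps * n_levels * 2
        total = n_ms + self.n_unisensory + self.n_catch
        if total != self.total_trials:
            raise ConfigurationError(
                f"breakdown sums to {total} trials ({n_ms} multisensory + "
                f"{self.n_unisensory} unisensory + {self.n_catch} catch) "
                f"but total_trials = {self.total_trials}"
            )
        for name, count in [
            ("multisensory_reps", self.multisensory_reps),
            ("n_unisensory", self.n_unisensory),
            ("n_catch", self.n_catch),
        ]:
            if count % self.n_blocks != 0:
                raise ConfigurationError(
                    f"{name} = {count} cannot be split evenly across {self.n_blocks} blocks"
                )


def _schedule_arrays(
    cfg: StimulusConfig, breakdown: TrialBreakdown
) -> dict[str, np.ndarray]:
    """One *block* worth of trial attributes, unshuffled (object arrays)."""
    modality, direction, label, delay_ms, dist_cm = [], [], [], [], []
    per_block = breakdown.multisensory_reps // breakdown.n_blocks
    for dirn in (LOOMING, RECEDING):
        for lv in distance_levels(cfg, dirn):
            for _ in range(per_block):
                modality.append(MULTISENSORY)
                direction.append(dirn)
                label.append(lv.label)
                delay_ms.append(lv.delay * 1000.0)
                dist_cm.append(lv.distance)
    for _ in range(breakdown.n_unisensory // breakdown.n_blocks):
        modality.append(UNISENSORY)
        direction.append(None)
        label.append(None)
        delay_ms.append(np.nan)
        dist_cm.append(np.nan)
    for _ in range(breakdown.n_catch // breakdown.n_blocks):
        modality.append(CATCH)
        direction.append(None)
        label.append(None)
        delay_ms.append(np.nan)
        dist_cm.append(np.nan)
    return {
        "modality": np.array(modality, dtype=object),
        "direction": np.array(direction, dtype=object),
        "distance_label": np.array(label, dtype=object),
        "delay_ms": np.array(delay_ms, dtype=float),
        "distance_cm": np.array(dist_cm, dtype=float),
    }


def build_session_schedule(
    cfg: StimulusConfig | None = None,
    seed: int | np.random.Generator = 0,
    breakdown: TrialBreakdown | None = None,
) -> pd.DataFrame:
    """Pseudo-randomized trial order for one session.

    Each block is balanced (every multisensory direction x distance cell gets
    ``multisensory_reps / n_blocks`` trials) and independently shuffled by the
    seeded generator; counts are invariant to the seed, only the order varies.
    """
    cfg = cfg or StimulusConfig()
    breakdown = breakdown or TrialBreakdown()
    breakdown.validate(len(cfg.tactile_delays))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    block_arrays = _schedule_arrays(cfg, breakdown)
    n_block = len(block_arrays["modality"])
    frames = []
    for block in range(1, breakdown.n_blocks + 1):
        order = rng.permutation(n_block)
        frames.append(
            pd.DataFrame({"block": block, **{k: v[order] for k, v in block_arrays.items()}})
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "trial_index", np.arange(1, len(out) + 1))
    return out[SCHEDULE_COLUMNS]


def schedule_to_csv(schedule: pd.DataFrame, path: str | Path) -> None:
    schedule.to_csv(path, index=False, columns=SCHEDULE_COLUMNS, float_format="%.6g")


def schedule_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"modality": object, "direction": object, "distance_label": object})
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"schedule file {path} is missing columns: {sorted(missing)}")
    for col in ("direction", "distance_label"):
        df[col] = df[col].where(pd.notna(df[col]), None)
    return df[SCHEDULE_COLUMNS]
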