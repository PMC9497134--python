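"""Synthetic visuo-tactile cohort generator.

Emulates trial-level reaction-time (RT) data with the statistical structure
the downstream analysis assumes: 22 participants, a fully within-subject
2 (experiment: real / virtual training) x 2 (session: pre / post) design, a
220-trial session schedule, distance-dependent multisensory facilitation of
tactile RTs, slower unisensory tactile RTs, and a peripersonal-space boundary
shift (a decrease of the point of subjective equality on the tap-delay axis)
applied only in the condition whose training is effective.

Model
-----
For a subject with baseline offset ``b ~ N(0, sd_between)`` and boundary
location ``pse_i ~ N(pse_pre, sd_pse_between)``, the expected multisensory RT
at tap delay ``t`` (ms) is a descending logistic on the delay axis::

    looming:  rt_far + b - A     * L((t - pse) / k)
    receding: rt_far + b + pen - A_rec * L((t - pse) / k)

with ``L`` the standard logistic function: far taps (small delays) stay near
the slow asymptote, near taps are facilitated by up to the amplitude ``A``.
Post-training sessions use ``pse = pse_i + shift`` with a per-experiment
shift. Unisensory tactile trials are centred on ``rt_unisensory + b``.
Trial noise is Gaussian on the ms scale truncated at ``rt_floor`` (a
shifted-lognormal option is available); missed trials are re-drawn so every
planned tactile trial yields one valid RT, mirroring the task's repeat rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from .errors import ConfigurationError, SchemaError
from .geometry import (
    CATCH,
    LOOMING,
    MULTISENSORY,
    RECEDING,
    UNISENSORY,
    StimulusConfig,
    TrialBreakdown,
    _schedule_arrays,
)

__all__ = [
    "GeneratorParams",
    "SubjectParams",
    "DISTANCE_MEAN_ANCHORS_MS",
    "EXPERIMENTS",
    "SESSIONS",
    "TRIAL_COLUMNS",
    "expected_multisensory_rt",
    "simulate_cohort",
    "export_trials",
]

EXPERIMENTS = ("real", "virtual")
SESSIONS = ("pre", "post")

TRIAL_COLUMNS = [
    "subject_id",
    "experiment",
    "session",
    "block",
    "trial_index",
    "modality",
    "direction",
    "distance_label",
    "delay_ms",
    "distance_cm",
    "rt_ms",
    "missed",
]

#: Reference group-mean looming RTs (ms) at each tap delay (ms), far (D1) to
#: near (D5), used by :meth:`GeneratorParams.calibrated` to anchor the
#: facilitation curve to observed per-distance means.
DISTANCE_MEAN_ANCHORS_MS: dict[float, float] = {
    433.0: 560.53,
    866.0: 535.31,
    1299.0: 515.53,
    1732.0: 499.28,
    2165.0: 498.48,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Population-level parameters of the synthetic cohort (all times in ms)."""

    n_subjects: int = 22
    pse_pre: float = 1277.5
    pse_shift_real: float = -109.9
    pse_shift_virtual: float = 0.0
    slope_k: float = 150.0
    rt_far_looming: float = 560.0
    facilitation_amp: float = 62.0
    receding_penalty: float = 15.0
    receding_facilitation_amp: float = 10.0
    rt_unisensory: float = 604.0
    sd_between: float = 40.0
    sd_pse_between: float = 120.0
    sd_trial: float = 90.0
    miss_rate: float = 0.01
    rt_floor: float = 150.0
    noise: str = "gaussian"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2 (inference needs paired data)")
        for name in ("sd_between", "sd_pse_between", "sd_trial"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.miss_rate < 1:
            raise ConfigurationError(f"miss_rate must be in [0, 1), got {self.miss_rate}")
        if self.facilitation_amp >= self.rt_far_looming:
            raise ConfigurationError("facilitation_amp must be smaller than rt_far_looming")
        if self.rt_unisensory <= self.rt_far_looming - self.facilitation_amp:
            raise ConfigurationError(
                "rt_unisensory must exceed the fastest multisensory asymptote "
                "(facilitation would otherwise reverse sign)"
            )
        if self.slope_k <= 0:
            raise ConfigurationError("slope_k must be > 0")
        if self.noise not in ("gaussian", "lognormal"):
            raise ConfigurationError(f"noise must be 'gaussian' or 'lognormal', got {self.noise!r}")

    def replace(self, **kw) -> "GeneratorParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"unknown generator parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def calibrated(cls, anchors: dict[float, float] | None = None, **overrides) -> "GeneratorParams":
        """Least-squares calibration of the facilitation curve to per-distance means.

        Fits (rt_far_looming, facilitation_amp, pse_pre, slope_k) so that the
        expected looming RT at each tap delay matches the anchor means; all
        other fields keep their defaults unless overridden.
        """
        anchors = anchors or DISTANCE_MEAN_ANCHORS_MS
        t = np.array(sorted(anchors), dtype=float)
        y = np.array([anchors[k] for k in sorted(anchors)], dtype=float)

        def model(tt, rt_far, amp, pse, k):
            return rt_far - amp * expit((tt - pse) / k)

        p0 = (y.max(), y.max() - y.min(), float(np.median(t)), 150.0)
        (rt_far, amp, pse, k), _ = curve_fit(
            model, t, y, p0=p0, bounds=([0, 0, t.min() - 2000, 1], [2000, 2000, t.max() + 2000, 5000])
        )
        return cls(**{
            "rt_far_looming": float(rt_far),
            "facilitation_amp": float(amp),
            "pse_pre": float(pse),
            "slope_k": float(k),
            **overrides,
        })


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject curve parameters after drawing the random offsets (ms)."""

    rt_far: float
    pse: float
    slope_k: float
    facilitation_amp: float
    receding_penalty: float
    receding_facilitation_amp: float
    rt_unisensory: float


def expected_multisensory_rt(
    delay_ms: float | np.ndarray, direction: str, subject: SubjectParams
) -> float | np.ndarray:
    """Noise-free multisensory RT (ms) at a tap delay for one subject."""
    z = (np.asarray(delay_ms, dtype=float) - subject.pse) / subject.slope_k
    if direction == LOOMING:
        out = subject.rt_far - subject.facilitation_amp * expit(z)
    elif direction == RECEDING:
        out = (
            subject.rt_far
            + subject.receding_penalty
            - subject.receding_facilitation_amp * expit(z)
        )
    else:
        raise ConfigurationError(f"direction must be {LOOMING!r} or {RECEDING!r}, got {direction!r}")
    return float(out) if np.isscalar(delay_ms) else out


def _draw_rts(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    floor: float,
    noise: str,
) -> np.ndarray:
    """Draw RTs around `mean` with the configured noise model, never below floor."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return np.maximum(mean, floor)
    if noise == "lognormal":
        shifted = np.maximum(mean - floor, 1e-6)
        sigma2 = np.log1p(sd**2 / shifted**2)
        mu = np.log(shifted) - sigma2 / 2.0
        return floor + rng.lognormal(mu, np.sqrt(sigma2))
    out = rng.normal(mean, sd)
    bad = out < floor  # truncated Gaussian via redraw
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd)
        bad = out < floor
    return out


def _session_rts(
    rng: np.random.Generator,
    params: GeneratorParams,
    subject: SubjectParams,
    modality: np.ndarray,
    direction: np.ndarray,
    delay_ms: np.ndarray,
) -> np.ndarray:
    """RTs for one 220-trial session; NaN for catch trials."""
    expected = np.full(len(modality), np.nan)
    for dirn in (LOOMING, RECEDING):
        m = (modality == MULTISENSORY) & (direction == dirn)
        if m.any():
            expected[m] = expected_multisensory_rt(delay_ms[m], dirn, subject)
    expected[modality == UNISENSORY] = subject.rt_unisensory
    tactile = modality != CATCH
    rts = np.full(len(modality), np.nan)
    rts[tactile] = _draw_rts(rng, expected[tactile], params.sd_trial, params.rt_floor, params.noise)
    if params.miss_rate > 0:
        # repeat-on-miss: a missed tap is re-delivered until a response lands
        idx = np.flatnonzero(tactile)
        missed = rng.random(idx.size) < params.miss_rate
        while missed.any():
            sel = idx[missed]
            rts[sel] = _draw_rts(rng, expected[sel], params.sd_trial, params.rt_floor, params.noise)
            idx = sel
            missed = rng.random(idx.size) < params.miss_rate
    return rts


def simulate_cohort(
    params: GeneratorParams | None = None,
    cfg: StimulusConfig | None = None,
    seed: int | np.random.Generator = 0,
    breakdown: TrialBreakdown | None = None,
) -> pd.DataFrame:
    """Simulate the full within-subject cohort as a trial-level table.

    Every subject contributes four sessions (real/virtual x pre/post), each a
    complete session schedule; the trial order is re-randomized per session.
    Fully reproducible given ``seed``. With defaults the result has
    ``22 * 4 * 220 = 19360`` rows.
    """
    params = params or GeneratorParams()
    cfg = cfg or StimulusConfig()
    breakdown = breakdown or TrialBreakdown()
    breakdown.validate(len(cfg.tactile_delays))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    block = _schedule_arrays(cfg, breakdown)
    n_block = len(block["modality"])
    n_session = n_block * breakdown.n_blocks
    shifts = {"real": params.pse_shift_real, "virtual": params.pse_shift_virtual}

    chunks: list[dict] = []
    for i in range(params.n_subjects):
        sid = f"S{i + 1:03d}"
        b = rng.normal(0.0, params.sd_between) if params.sd_between > 0 else 0.0
        pse_i = (
            rng.normal(params.pse_pre, params.sd_pse_between)
            if params.sd_pse_between > 0
            else params.pse_pre
        )
        for exp in EXPERIMENTS:
            for sess in SESSIONS:
                pse_cell = pse_i + (shifts[exp] if sess == "post" else 0.0)
                subject = SubjectParams(
                    rt_far=params.rt_far_looming + b,
                    pse=pse_cell,
                    slope_k=params.slope_k,
                    facilitation_amp=params.facilitation_amp,
                    receding_penalty=params.receding_penalty,
                    receding_facilitation_amp=params.receding_facilitation_amp,
                    rt_unisensory=params.rt_unisensory + b,
                )
                orders = [rng.permutation(n_block) for _ in range(breakdown.n_blocks)]
                cols = {
                    k: np.concatenate([block[k][o] for o in orders])
                    for k in ("modality", "direction", "distance_label", "delay_ms", "distance_cm")
                }
                rts = _session_rts(
                    rng, params, subject, cols["modality"], cols["direction"], cols["delay_ms"]
                )
                chunks.append(
                    {
                        "subject_id": np.repeat(sid, n_session),
                        "experiment": np.repeat(exp, n_session),
                        "session": np.repeat(sess, n_session),
                        "block": np.repeat(np.arange(1, breakdown.n_blocks + 1), n_block),
                        "trial_index": np.arange(1, n_session + 1),
                        **cols,
                        "rt_ms": rts,
                        "missed": np.zeros(n_session, dtype=bool),
                    }
                )
    data = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
    return pd.DataFrame(data)[TRIAL_COLUMNS]


def export_trials(records: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical CSV schema.

    Missing RTs (missed trials, visual-only catch trials) become empty fields;
    the `missed` flag is written as ``True``/``False``.
    """
    if len(records) == 0:
        raise SchemaError("refusing to export an empty trial table")
    missing = set(TRIAL_COLUMNS) - set(records.columns)
    if missing:
        raise SchemaError(f"trial table is missing columns: {sorted(missing)}")
    records.to_csv(path, index=False, columns=TRIAL_COLUMNS)
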