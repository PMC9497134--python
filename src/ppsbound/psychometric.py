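"""Per-subject psychometric curves and Spearman-Karber boundary estimates.

The peripersonal-space boundary is read out from how much an approaching
visual stimulus speeds tactile reaction times (RTs). For one subject and
condition, mean looming multisensory RTs at the five tap delays are rescaled
into facilitation proportions (0 at the slowest level, 1 at the fastest),
monotonized by pool-adjacent-violators, and treated as an empirical response
function on the delay axis. The Spearman-Karber (SK) method then reads the
curve as the CDF of a latent threshold distribution:

* PSE (point of subjective equality) — the SK mean, the delay at which
  facilitation reaches its midpoint; the proxy for the boundary location.
* DL (difference limen) — half the interquartile spread of the SK-implied
  distribution; the proxy for the boundary's sharpness.

Because an observed curve need not reach 0 or 1 at the tested extremes, the
curve is augmented with virtual levels one delay-spacing outside the tested
range carrying proportions 0 and 1 before the SK integrals are taken; this
keeps the estimator well defined and bounded by the augmented range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .errors import EstimationError
from .geometry import LOOMING, MULTISENSORY, StimulusConfig, pse_time_to_distance

__all__ = [
    "FilterRules",
    "PsychometricCurve",
    "BoundaryEstimate",
    "filter_rts",
    "aggregate_mean_rts",
    "facilitation_proportions",
    "monotonize",
    "sk_pse",
    "sk_dl",
    "estimate_boundary",
    "estimate_all",
    "estimates_to_csv",
]

CELL_KEYS = ["subject_id", "experiment", "session"]


@dataclass(frozen=True)
class FilterRules:
    """RT cleaning rules: drop missed trials and RTs outside [rt_min, rt_max] ms."""

    rt_min: float = 150.0
    rt_max: float = 1500.0


def filter_rts(
    records: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove missed trials and out-of-window RTs.

    Returns the retained records and an exclusion log with per-rule counts.
    Rows that never carry an RT (visual-only catch trials) are kept: they are
    not RT observations and no rule applies to them. Raises
    :class:`EstimationError` if every valid trial of a multisensory cell that
    was present in the input is removed.
    """
    rules = rules or FilterRules()
    missed = records["missed"].fillna(False).astype(bool)
    has_rt = records["rt_ms"].notna()
    below = has_rt & ~missed & (records["rt_ms"] < rules.rt_min)
    above = has_rt & ~missed & (records["rt_ms"] > rules.rt_max)
    keep = ~(missed | below | above)
    log = {
        "missed": int(missed.sum()),
        "below_floor": int(below.sum()),
        "above_ceiling": int(above.sum()),
    }
    out = records.loc[keep]

    ms_in = records[(records["modality"] == MULTISENSORY) & has_rt & ~missed.values]
    if len(ms_in):
        keys = CELL_KEYS + ["direction", "distance_label"]
        present = set(map(tuple, ms_in[keys].drop_duplicates().itertuples(index=False)))
        ms_out = out[(out["modality"] == MULTISENSORY) & out["rt_ms"].notna()]
        surviving = set(map(tuple, ms_out[keys].drop_duplicates().itertuples(index=False)))
        lost = present - surviving
        if lost:
            cell = sorted(lost)[0]
            raise EstimationError(
                f"RT filtering removed every trial of cell {dict(zip(keys, cell))}"
            )
    return out, log


def aggregate_mean_rts(
    records: pd.DataFrame,
    by: Iterable[str] = ("subject_id", "experiment", "session", "modality", "direction", "distance_label"),
) -> pd.DataFrame:
    """Arithmetic mean RT and trial count per cell.

    Only rows carrying an RT contribute. Grouping keys that are undefined for
    a modality (e.g. distance for unisensory trials) form their own cell.
    """
    valid = records[records["rt_ms"].notna()]
    if len(valid) == 0:
        raise EstimationError("no valid RTs to aggregate")
    by = list(by)
    grouped = (
        valid.groupby(by, dropna=False, sort=True, observed=True)["rt_ms"]
        .agg(mean_rt_ms="mean", n_trials="count")
        .reset_index()
    )
    return grouped


@dataclass(frozen=True)
class PsychometricCurve:
    """Facilitation proportion as a function of tap delay for one cell."""

    x: np.ndarray  # delay levels, ms, strictly increasing
    p: np.ndarray  # facilitation proportions in [0, 1]
    n_trials_per_level: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "p", p)
        if x.ndim != 1 or p.shape != x.shape or len(x) < 3:
            raise EstimationError("curve needs >= 3 (delay, proportion) pairs")
        if np.any(np.diff(x) <= 0):
            raise EstimationError("delay levels must be strictly increasing")
        if np.any((p < -1e-12) | (p > 1 + 1e-12)):
            raise EstimationError("proportions must lie in [0, 1]")

    def monotonized(self) -> "PsychometricCurve":
        return PsychometricCurve(self.x, monotonize(self.p), self.n_trials_per_level)


def facilitation_proportions(
    mean_rts: Iterable[float],
    delays_ms: Iterable[float],
    n_trials: Iterable[int] | None = None,
) -> PsychometricCurve:
    """Rescale per-level mean RTs to facilitation proportions.

    ``p_k = (RT_max - RT_k) / (RT_max - RT_min)`` with the extrema taken over
    the levels of this curve, so the slowest level maps to 0 and the fastest
    to 1. Flat curves carry no facilitation signal and raise
    :class:`EstimationError`.
    """
    rt = np.asarray(list(mean_rts), dtype=float)
    x = np.asarray(list(delays_ms), dtype=float)
    if rt.shape != x.shape:
        raise EstimationError("mean_rts and delays_ms must have equal length")
    hi, lo = rt.max(), rt.min()
    if hi == lo:
        raise EstimationError("degenerate psychometric curve: all mean RTs equal (no facilitation)")
    p = (hi - rt) / (hi - lo)
    n = None if n_trials is None else np.asarray(list(n_trials), dtype=int)
    return PsychometricCurve(x=x, p=p, n_trials_per_level=n)


def monotonize(p: Iterable[float]) -> np.ndarray:
    """Nondecreasing least-squares projection (pool-adjacent-violators)."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    return np.clip(isotonic_regression(arr, increasing=True).x, 0.0, 1.0)


def _augmented(curve: PsychometricCurve, spacing: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Monotone curve extended with virtual 0/1 levels outside the tested range."""
    x, p = curve.x, curve.p
    if np.any(np.diff(p) < -1e-9):
        raise EstimationError("Spearman-Karber needs a nondecreasing curve; monotonize first")
    p = np.clip(p, 0.0, 1.0)
    step = spacing if spacing is not None else float(np.mean(np.diff(x)))
    if p[0] > 0:
        x = np.concatenate([[x[0] - step], x])
        p = np.concatenate([[0.0], p])
    if p[-1] < 1:
        x = np.concatenate([x, [x[-1] + step]])
        p = np.concatenate([p, [1.0]])
    if p[-1] - p[0] <= 0:
        raise EstimationError("degenerate curve: no increase after monotonization")
    return x, p


def sk_pse(curve: PsychometricCurve, spacing: float | None = None) -> float:
    """Spearman-Karber location estimate: the mean of the implied distribution.

    ``PSE = sum_k (x_k + x_{k+1}) / 2 * (p_{k+1} - p_k)`` over the augmented
    curve, i.e. the probability mass between consecutive levels is assigned to
    their midpoint.
    """
    x, p = _augmented(curve, spacing)
    mid = (x[:-1] + x[1:]) / 2.0
    return float(np.sum(mid * np.diff(p)))


def _sk_quantile(x: np.ndarray, p: np.ndarray, q: float) -> float:
    """Quantile of the SK-implied distribution by linear interpolation of the curve."""
    j = int(np.searchsorted(p, q, side="left"))
    if j == 0:
        return float(x[0])
    if j == len(p):
        return float(x[-1])
    lo = j - 1
    while lo > 0 and p[lo] == p[j]:  # skip flat segments: cross at the rising edge
        lo -= 1
    if p[j] == p[lo]:
        return float(x[j])
    frac = (q - p[lo]) / (p[j] - p[lo])
    return float(x[lo] + frac * (x[j] - x[lo]))


def sk_dl(curve: PsychometricCurve, spacing: float | None = None) -> float:
    """Spearman-Karber spread estimate: half the interquartile range.

    Quartiles of the implied distribution are obtained by linear interpolation
    of the monotonized, augmented curve; ``DL = (Q75 - Q25) / 2``.
    """
    x, p = _augmented(curve, spacing)
    q25 = _sk_quantile(x, p, 0.25)
    q75 = _sk_quantile(x, p, 0.75)
    return float((q75 - q25) / 2.0)


@dataclass(frozen=True)
class BoundaryEstimate:
    """Spearman-Karber boundary estimate for one subject x experiment x session."""

    subject_id: str
    experiment: str
    session: str
    pse_ms: float
    dl_ms: float
    pse_cm: float
    n_valid_trials: int


def estimate_boundary(
    records: pd.DataFrame,
    cfg: StimulusConfig | None = None,
    rules: FilterRules | None = None,
    prefiltered: bool = False,
) -> BoundaryEstimate:
    """Full estimation chain for the trials of ONE subject x experiment x session.

    filter -> per-level looming means -> facilitation proportions ->
    monotonize -> SK PSE and DL. Only multisensory looming trials enter the
    curve; the PSE is also expressed as a body-centred distance (cm).
    """
    cfg = cfg or StimulusConfig()
    cells = records[CELL_KEYS].drop_duplicates()
    if len(cells) != 1:
        raise EstimationError(
            f"estimate_boundary expects one subject x experiment x session, got {len(cells)} cells"
        )
    sid, exp, sess = cells.iloc[0]
    try:
        if not prefiltered:
            records, _ = filter_rts(records, rules)
        looming = records[
            (records["modality"] == MULTISENSORY)
            & (records["direction"] == LOOMING)
            & records["rt_ms"].notna()
        ]
        if len(looming) == 0:
            raise EstimationError("no valid multisensory looming trials (looming required)")
        means = looming.groupby("delay_ms", sort=True)["rt_ms"].agg(["mean", "count"])
        expected = np.round(cfg.delays_ms, 6)
        got = np.round(means.index.to_numpy(dtype=float), 6)
        missing = sorted(set(expected) - set(got))
        if missing:
            raise EstimationError(f"no valid looming trials at delay(s) {missing} ms")
        curve = facilitation_proportions(
            means["mean"].to_numpy(), means.index.to_numpy(dtype=float), means["count"].to_numpy()
        ).monotonized()
        pse = sk_pse(curve)
        dl = sk_dl(curve)
    except EstimationError as err:
        raise EstimationError(
            f"subject {sid}, experiment {exp}, session {sess}: {err}"
        ) from err
    return BoundaryEstimate(
        subject_id=str(sid),
        experiment=str(exp),
        session=str(sess),
        pse_ms=pse,
        dl_ms=dl,
        pse_cm=pse_time_to_distance(pse, cfg),
        n_valid_trials=int(means["count"].sum()),
    )


def estimate_all(
    records: pd.DataFrame,
    cfg: StimulusConfig | None = None,
    rules: FilterRules | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Boundary estimates for every subject x experiment x session in a table."""
    cfg = cfg or StimulusConfig()
    if not prefiltered:
        records, _ = filter_rts(records, rules)
    looming = records[
        (records["modality"] == MULTISENSORY)
        & (records["direction"] == LOOMING)
        & records["rt_ms"].notna()
    ]
    if len(looming) == 0:
        raise EstimationError("no valid multisensory looming trials in the table")
    means = (
        looming.groupby(CELL_KEYS + ["delay_ms"], sort=True, observed=True)["rt_ms"]
        .agg(["mean", "count"])
        .reset_index()
    )
    expected = np.round(cfg.delays_ms, 6)
    rows = []
    for (sid, exp, sess), g in means.groupby(CELL_KEYS, sort=True):
        got = np.round(g["delay_ms"].to_numpy(dtype=float), 6)
        missing = sorted(set(expected) - set(got))
        if missing:
            raise EstimationError(
                f"subject {sid}, experiment {exp}, session {sess}: "
                f"no valid looming trials at delay(s) {missing} ms"
            )
        try:
            curve = facilitation_proportions(
                g["mean"].to_numpy(), g["delay_ms"].to_numpy(dtype=float), g["count"].to_numpy()
            ).monotonized()
            pse = sk_pse(curve)
            dl = sk_dl(curve)
        except EstimationError as err:
            raise EstimationError(
                f"subject {sid}, experiment {exp}, session {sess}: {err}"
            ) from err
        rows.append(
            {
                "subject_id": sid,
                "experiment": exp,
                "session": sess,
                "pse_ms": pse,
                "pse_cm": pse_time_to_distance(pse, cfg),
                "dl_ms": dl,
                "n_valid_trials": int(g["count"].sum()),
            }
        )
    return pd.DataFrame(rows)


def estimates_to_csv(estimates: pd.DataFrame, path) -> None:
    cols = ["subject_id", "experiment", "session", "pse_ms", "pse_cm", "dl_ms", "n_valid_trials"]
    estimates.to_csv(path, index=False, columns=cols)
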