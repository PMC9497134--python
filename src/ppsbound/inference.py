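"""Within-subject factorial inference: repeated-measures ANOVA and Newman-Keuls.

Implements the classical fully-within-subject variance decomposition for one
or two factors. Every subject contributes one value per cell; each effect is
tested against its own subject-by-effect interaction error term::

    F_effect = MS_effect / MS_(effect x subject)

Effect sizes are partial eta-squared, ``SS_effect / (SS_effect + SS_error)``.
No sphericity correction is applied by default; a Greenhouse-Geisser
correction is available behind a flag. Post-hoc comparisons use the
Newman-Keuls step-down procedure on ordered means with studentized-range
critical values that shrink with the span of the pair being tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EstimationError

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "rm_anova",
    "partial_eta_sq",
    "studentized_range_cdf",
    "studentized_range_ppf",
    "newman_keuls",
    "facilitation_test",
]


@dataclass(frozen=True)
class AnovaResult:
    """One effect of a within-subject ANOVA."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float
    ms_error: float
    ss_effect: float
    ss_error: float
    eps: float | None = None  # Greenhouse-Geisser epsilon, when requested
    p_gg: float | None = None

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
            "eta_p2": self.eta_p2,
            "ms_error": self.ms_error,
            "ss_effect": self.ss_effect,
            "ss_error": self.ss_error,
            "eps": self.eps,
            "p_gg": self.p_gg,
        }


@dataclass(frozen=True)
class PosthocResult:
    """One ordered pair of a Newman-Keuls run (lower-mean label first)."""

    pair: tuple[str, str]
    diff: float  # higher mean minus lower mean
    r: int  # number of ordered means spanned, inclusive
    q_crit: float
    q_stat: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "diff": self.diff,
            "r": self.r,
            "q_crit": self.q_crit,
            "q_stat": self.q_stat,
            "significant": self.significant,
        }


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    """Partial eta-squared effect size: ``SS_effect / (SS_effect + SS_error)``."""
    if ss_effect < 0 or ss_error < 0:
        raise EstimationError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise EstimationError("partial eta-squared undefined: both sums of squares are zero")
    return ss_effect / (ss_effect + ss_error)


def _cube(data: pd.DataFrame, dv: str, within: list[str], subject: str) -> tuple[np.ndarray, list, list, list]:
    """Pivot long data into an (n_subjects, a, b) cube, validating balance."""
    factors = list(within)
    if not 1 <= len(factors) <= 2:
        raise ConfigurationError("rm_anova supports one or two within factors")
    cols = [subject, *factors, dv]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ConfigurationError(f"data is missing columns: {missing}")
    subjects = sorted(data[subject].unique())
    if len(subjects) < 2:
        raise ConfigurationError("need at least 2 subjects for within-subject inference")
    levels = [sorted(data[f].unique()) for f in factors]
    counts = data.groupby([subject, *factors], observed=True)[dv].count()
    expected = pd.MultiIndex.from_product([subjects, *levels], names=[subject, *factors])
    absent = expected.difference(counts.index)
    if len(absent):
        raise ConfigurationError(f"incomplete design; missing cells: {list(absent[:10])}")
    if (counts != 1).any():
        dup = counts[counts != 1].index[:10]
        raise ConfigurationError(f"expected exactly one value per subject x cell; offending: {list(dup)}")
    wide = data.set_index([subject, *factors])[dv].reindex(expected)
    shape = (len(subjects), *[len(lv) for lv in levels])
    cube = wide.to_numpy(dtype=float).reshape(shape)
    if cube.ndim == 2:
        cube = cube[:, :, None]
        levels = [levels[0], [None]]
    return cube, subjects, levels[0], levels[1]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the centred subspace."""
    basis = np.eye(k) - np.full((k, k), 1.0 / k)
    q, _ = np.linalg.qr(basis)
    return q[:, : k - 1]


def _gg_epsilon(diffs: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject scores on orthonormal contrasts."""
    d = diffs.shape[1]
    if d <= 1:
        return 1.0
    s = np.cov(diffs, rowvar=False)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    denom = d * np.sum(s * s)
    if denom == 0:
        return 1.0
    return float(np.clip(tr**2 / denom, 1.0 / d, 1.0))


def _result(name, ss_eff, ss_err, df_num, df_den, eps=None) -> AnovaResult:
    ms_eff = ss_eff / df_num
    ms_err = ss_err / df_den
    if ms_err == 0:
        f_val = 0.0 if ss_eff == 0 else np.inf
    else:
        f_val = ms_eff / ms_err
    p = float(stats.f.sf(f_val, df_num, df_den)) if np.isfinite(f_val) else 0.0
    if ss_eff == 0 and ss_err == 0:
        eta = 0.0
    else:
        eta = partial_eta_sq(ss_eff, ss_err)
    p_gg = None
    if eps is not None and np.isfinite(f_val):
        p_gg = float(stats.f.sf(f_val, eps * df_num, eps * df_den))
    return AnovaResult(
        effect=name,
        F=float(f_val),
        df_num=int(df_num),
        df_den=int(df_den),
        p=p,
        eta_p2=float(eta),
        ms_error=float(ms_err),
        ss_effect=float(ss_eff),
        ss_error=float(ss_err),
        eps=None if eps is None else float(eps),
        p_gg=p_gg,
    )


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject_id",
    correction: str = "none",
) -> list[AnovaResult]:
    """Fully within-subject ANOVA with one or two factors.

    Parameters
    ----------
    data : long-format table, one row per subject x cell.
    dv : name of the value column.
    within : one or two factor column names.
    subject : subject identifier column.
    correction : ``"none"`` (default) or ``"gg"`` for Greenhouse-Geisser
        corrected p-values (reported alongside the uncorrected ones).

    Returns the main effect(s) and, for two factors, their interaction, each
    tested against its own subject-interaction error term.
    """
    if correction not in ("none", "gg"):
        raise ConfigurationError(f"correction must be 'none' or 'gg', got {correction!r}")
    within = list(within)
    cube, subjects, lv_a, lv_b = _cube(data, dv, within, subject)
    n, a, b = cube.shape
    gm = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)
    m_as = cube.mean(axis=2)
    m_bs = cube.mean(axis=1)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + gm) ** 2)

    want_gg = correction == "gg"
    eps_a = _gg_epsilon(m_as @ _orthonormal_contrasts(a)) if want_gg else None
    results = [_result(within[0], ss_a, ss_as, a - 1, (a - 1) * (n - 1), eps_a)]

    if len(within) == 2:
        ss_b = n * a * np.sum((m_b - gm) ** 2)
        ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2)
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
        resid = (
            cube
            - m_ab[None, :, :]
            - m_as[:, :, None]
            - m_bs[:, None, :]
            + m_a[None, :, None]
            + m_b[None, None, :]
            + m_s[:, None, None]
            - gm
        )
        ss_abs = np.sum(resid**2)
        eps_b = _gg_epsilon(m_bs @ _orthonormal_contrasts(b)) if want_gg else None
        c_ab = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
        eps_ab = _gg_epsilon(cube.reshape(n, a * b) @ c_ab) if want_gg else None
        results.append(_result(within[1], ss_b, ss_bs, b - 1, (b - 1) * (n - 1), eps_b))
        results.append(
            _result(
                f"{within[0]} x {within[1]}",
                ss_ab,
                ss_abs,
                (a - 1) * (b - 1),
                (a - 1) * (b - 1) * (n - 1),
                eps_ab,
            )
        )
    return results


def studentized_range_cdf(q: float, r: int, df: float) -> float:
    """P(Q <= q) for the studentized range of ``r`` means with ``df`` error dof."""
    if r < 2 or int(r) != r:
        raise ConfigurationError(f"r must be an integer >= 2, got {r}")
    if df < 1:
        raise ConfigurationError(f"df must be >= 1, got {df}")
    if q < 0:
        raise ConfigurationError(f"q must be >= 0, got {q}")
    if q == 0:
        return 0.0
    return float(stats.studentized_range.cdf(q, r, df))


def studentized_range_ppf(p: float, r: int, df: float) -> float:
    """Inverse of :func:`studentized_range_cdf` in its second argument."""
    if not 0 < p < 1:
        raise ConfigurationError(f"p must be in (0, 1), got {p}")
    if r < 2 or int(r) != r:
        raise ConfigurationError(f"r must be an integer >= 2, got {r}")
    if df < 1:
        raise ConfigurationError(f"df must be >= 1, got {df}")
    return float(stats.studentized_range.ppf(p, r, df))


def newman_keuls(
    cell_means: Mapping[str, float],
    n_per_mean: int | Sequence[int],
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> list[PosthocResult]:
    """Newman-Keuls step-down comparisons on a family of cell means.

    Means are ordered ascending (ties broken by label order); the widest pair
    is tested at range span ``r = m`` and spans shrink stepping down. A pair
    is significant iff its studentized range statistic exceeds the critical
    value at its span AND every enclosing pair was significant (containment:
    pairs nested inside a non-significant span are declared non-significant
    without testing).
    """
    labels = list(cell_means)
    if len(labels) < 2:
        raise ConfigurationError("need at least 2 means")
    if ms_error <= 0:
        raise ConfigurationError("ms_error must be > 0")
    if np.ndim(n_per_mean) > 0:
        ns = list(n_per_mean)
        if len(ns) != len(labels):
            raise ConfigurationError(
                f"n_per_mean has {len(ns)} entries for {len(labels)} means"
            )
        if len(set(ns)) != 1:
            raise ConfigurationError(f"unequal n per mean not supported: {ns}")
        n = int(ns[0])
    else:
        n = int(n_per_mean)
    order = sorted(labels, key=lambda lab: (cell_means[lab], lab))
    means = np.array([cell_means[lab] for lab in order], dtype=float)
    m = len(order)
    se = float(np.sqrt(ms_error / n))
    results: list[PosthocResult] = []
    nonsig_spans: list[tuple[int, int]] = []
    for r in range(m, 1, -1):
        q_crit = studentized_range_ppf(1 - alpha, r, df_error)
        for lo in range(0, m - r + 1):
            hi = lo + r - 1
            diff = means[hi] - means[lo]
            q_stat = diff / se
            contained = any(l <= lo and hi <= h for l, h in nonsig_spans)
            sig = (not contained) and (q_stat > q_crit)
            if not sig:
                nonsig_spans.append((lo, hi))
            results.append(
                PosthocResult(
                    pair=(order[lo], order[hi]),
                    diff=float(diff),
                    r=r,
                    q_crit=float(q_crit),
                    q_stat=float(q_stat),
                    significant=bool(sig),
                )
            )
    return results


def facilitation_test(
    multisensory_means: Sequence[float], unisensory_means: Sequence[float]
) -> AnovaResult:
    """One-factor (modality: multisensory vs unisensory) within-subject ANOVA.

    Takes per-subject mean RTs, paired by position; equivalent to the squared
    paired t statistic on the difference.
    """
    multi = np.asarray(multisensory_means, dtype=float)
    uni = np.asarray(unisensory_means, dtype=float)
    if multi.shape != uni.shape or multi.ndim != 1:
        raise ConfigurationError("multisensory and unisensory means must be paired per subject")
    n = len(multi)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), 2),
            "modality": np.tile(["multisensory", "unisensory"], n),
            "rt": np.column_stack([multi, uni]).ravel(),
        }
    )
    return rm_anova(df, dv="rt", within=["modality"], subject="subject_id")[0]
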