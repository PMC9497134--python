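"""End-to-end analysis pipeline: trial table -> boundary estimates -> inference.

Mirrors the study's reporting structure: per-subject boundary estimates,
group means +/- SE per condition, a Condition (pre/post) x Experiment
(real/virtual) within-subject ANOVA on the point of subjective equality (PSE)
and on the difference limen (DL), Newman-Keuls post-hoc comparisons on
significant interactions, and a multisensory-vs-unisensory facilitation test.
Every number in a report is recomputable from the trial CSV and the run
configuration alone; reports carry a provenance block (config hash, seed,
package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import GeneratorParams, TRIAL_COLUMNS
from .errors import ConfigurationError, SchemaError
from .geometry import LOOMING, MULTISENSORY, UNISENSORY, StimulusConfig
from .inference import (
    AnovaResult,
    PosthocResult,
    facilitation_test,
    newman_keuls,
    rm_anova,
)
from .psychometric import FilterRules, estimate_all, filter_rts

__all__ = ["RunConfig", "Report", "load_trials", "run_analysis", "render_report_text"]

_REQUIRED_COLUMNS = set(TRIAL_COLUMNS)
_STRING_COLUMNS = ["subject_id", "experiment", "session", "modality", "direction", "distance_label"]


def load_trials(path: str | Path) -> pd.DataFrame:
    """Load a trial-level CSV, validating the schema.

    Unknown columns are preserved but ignored downstream; row numbers (header
    = row 1) are used in error messages. Empty ``rt_ms`` fields mean no
    response was recorded for that trial.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"trial file not found: {path}")
    df = pd.read_csv(path, dtype={c: object for c in _STRING_COLUMNS})
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise SchemaError(f"trial file {path} is missing required column(s): {sorted(missing)}")
    raw_rt = df["rt_ms"]
    rt = pd.to_numeric(raw_rt, errors="coerce")
    raw_str = raw_rt.astype(str).str.strip()
    bad = rt.isna() & raw_rt.notna() & (raw_str != "") & (raw_str.str.lower() != "nan")
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise SchemaError(f"trial file {path}: unparsable rt_ms {raw_rt[bad.idxmax()]!r} at row {row}")
    df["rt_ms"] = rt
    for col in ("delay_ms", "distance_cm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["missed"] = (
        df["missed"].astype(str).str.strip().str.lower().map(
            {"true": True, "1": True, "false": False, "0": False, "": False, "nan": False}
        )
    )
    if df["missed"].isna().any():
        row = int(df["missed"].isna().idxmax()) + 2
        raise SchemaError(f"trial file {path}: unparsable missed flag at row {row}")
    df["missed"] = df["missed"].astype(bool)
    for col in ("direction", "distance_label"):
        df[col] = df[col].where(pd.notna(df[col]), None)
    return df


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs besides the trial table itself."""

    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    filters: FilterRules = field(default_factory=FilterRules)
    alpha: float = 0.05
    sphericity_correction: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sphericity_correction not in ("none", "gg"):
            raise ConfigurationError("sphericity_correction must be 'none' or 'gg'")

    def to_dict(self) -> dict:
        return {
            "stimulus": self.stimulus.to_dict(),
            "generator": self.generator.to_dict(),
            "filters": {"rt_min_ms": self.filters.rt_min, "rt_max_ms": self.filters.rt_max},
            "alpha": self.alpha,
            "sphericity_correction": self.sphericity_correction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"stimulus", "generator", "filters", "alpha", "sphericity_correction", "seed"}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown run config keys: {sorted(unknown)}")
        filt = d.get("filters", {})
        return cls(
            stimulus=StimulusConfig.from_dict(d.get("stimulus", {})),
            generator=GeneratorParams.from_dict(d.get("generator", {})),
            filters=FilterRules(
                rt_min=float(filt.get("rt_min_ms", FilterRules.rt_min)),
                rt_max=float(filt.get("rt_max_ms", FilterRules.rt_max)),
            ),
            alpha=float(d.get("alpha", 0.05)),
            sphericity_correction=str(d.get("sphericity_correction", "none")),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form, excluding the seed.

        The hash identifies the analysis configuration; the seed is reported
        separately in provenance so reruns of the same config under different
        seeds are recognizably the same analysis.
        """
        payload = {k: v for k, v in self.to_dict().items() if k != "seed"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class Report:
    """Analysis output: estimates, group summaries, inference, provenance."""

    estimates: pd.DataFrame
    group_summary: pd.DataFrame
    anova_pse: list[AnovaResult]
    anova_dl: list[AnovaResult]
    posthoc_pse: list[PosthocResult]
    posthoc_dl: list[PosthocResult]
    facilitation: dict
    exclusions: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(orient="records"),
            "group_summary": self.group_summary.to_dict(orient="records"),
            "anova_pse": [r.to_dict() for r in self.anova_pse],
            "anova_dl": [r.to_dict() for r in self.anova_dl],
            "posthoc_pse": [r.to_dict() for r in self.posthoc_pse],
            "posthoc_dl": [r.to_dict() for r in self.posthoc_dl],
            "facilitation": self.facilitation,
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def run_analysis(config: RunConfig, trials: pd.DataFrame) -> Report:
    """Run the full analysis on a trial table; deterministic given inputs."""
    subjects = trials["subject_id"].unique()
    if len(subjects) < 2:
        raise ConfigurationError("analysis needs trials from at least 2 subjects")
    sessions = set(trials["session"].unique())
    if not {"pre", "post"} <= sessions:
        raise ConfigurationError(f"analysis needs both 'pre' and 'post' sessions, got {sorted(sessions)}")

    filtered, exclusions = filter_rts(trials, config.filters)
    estimates = estimate_all(filtered, config.stimulus, prefiltered=True)

    anova_pse = rm_anova(
        estimates, dv="pse_ms", within=["session", "experiment"],
        correction=config.sphericity_correction,
    )
    anova_dl = rm_anova(
        estimates, dv="dl_ms", within=["session", "experiment"],
        correction=config.sphericity_correction,
    )

    n_subj = estimates["subject_id"].nunique()

    def _posthoc(est_col: str, interaction: AnovaResult) -> list[PosthocResult]:
        if interaction.p >= config.alpha:
            return []
        cells = estimates.groupby(["experiment", "session"], observed=True)[est_col].mean()
        means = {f"{exp}:{sess}": float(v) for (exp, sess), v in cells.items()}
        return newman_keuls(
            means,
            n_per_mean=n_subj,
            ms_error=interaction.ms_error,
            df_error=interaction.df_den,
            alpha=config.alpha,
        )

    posthoc_pse = _posthoc("pse_ms", anova_pse[-1])
    posthoc_dl = _posthoc("dl_ms", anova_dl[-1])

    group_summary = (
        estimates.groupby(["experiment", "session"], observed=True)
        .agg(
            n=("pse_ms", "count"),
            pse_mean_ms=("pse_ms", "mean"),
            pse_se_ms=("pse_ms", _sem),
            dl_mean_ms=("dl_ms", "mean"),
            dl_se_ms=("dl_ms", _sem),
            pse_mean_cm=("pse_cm", "mean"),
        )
        .reset_index()
    )

    valid = filtered[filtered["rt_ms"].notna()]
    multi = (
        valid[(valid["modality"] == MULTISENSORY) & (valid["direction"] == LOOMING)]
        .groupby("subject_id", observed=True)["rt_ms"].mean()
    )
    uni = valid[valid["modality"] == UNISENSORY].groupby("subject_id", observed=True)["rt_ms"].mean()
    common = multi.index.intersection(uni.index)
    fac_anova = facilitation_test(multi.loc[common].to_numpy(), uni.loc[common].to_numpy())
    facilitation = {
        "anova": fac_anova.to_dict(),
        "multisensory_mean_ms": float(multi.loc[common].mean()),
        "multisensory_se_ms": _sem(multi.loc[common].to_numpy()),
        "unisensory_mean_ms": float(uni.loc[common].mean()),
        "unisensory_se_ms": _sem(uni.loc[common].to_numpy()),
        "n": int(len(common)),
    }

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_subjects": int(n_subj),
        "n_trials_in": int(len(trials)),
        "n_trials_retained": int(len(filtered)),
    }
    return Report(
        estimates=estimates,
        group_summary=group_summary,
        anova_pse=anova_pse,
        anova_dl=anova_dl,
        posthoc_pse=posthoc_pse,
        posthoc_dl=posthoc_dl,
        facilitation=facilitation,
        exclusions=exclusions,
        provenance=provenance,
    )


def _fmt_anova(rows: list[dict]) -> list[str]:
    out = []
    for r in rows:
        line = (
            f"  {r['effect']:<24s} F({r['df_num']},{r['df_den']}) = {r['F']:.2f}, "
            f"p = {r['p']:.4f}, eta_p2 = {r['eta_p2']:.2f}"
        )
        if r.get("p_gg") is not None:
            line += f" (GG eps = {r['eps']:.3f}, p_gg = {r['p_gg']:.4f})"
        out.append(line)
    return out


def render_report_text(report: dict | Report) -> str:
    """Human-readable rendering of a report (or its JSON dict form)."""
    d = report.to_dict() if isinstance(report, Report) else report
    lines = ["Peripersonal-space boundary analysis", "=" * 38, ""]
    lines.append("Group boundary estimates (mean +/- SE over subjects):")
    for g in d["group_summary"]:
        lines.append(
            f"  {g['experiment']:>7s} / {g['session']:<4s}  "
            f"PSE = {g['pse_mean_ms']:7.2f} +/- {g['pse_se_ms']:5.2f} ms "
            f"({g['pse_mean_cm']:6.2f} cm), DL = {g['dl_mean_ms']:6.2f} +/- {g['dl_se_ms']:5.2f} ms "
            f"(n = {g['n']})"
        )
    lines += ["", "ANOVA on PSE (Condition x Experiment, within subjects):"]
    lines += _fmt_anova(d["anova_pse"])
    lines += ["", "ANOVA on DL (Condition x Experiment, within subjects):"]
    lines += _fmt_anova(d["anova_dl"])
    for key, name in (("posthoc_pse", "PSE"), ("posthoc_dl", "DL")):
        if d[key]:
            lines += ["", f"Newman-Keuls on the {name} interaction cells:"]
            for p in d[key]:
                star = "*" if p["significant"] else " "
                lines.append(
                    f" {star} {p['pair'][0]:<13s} vs {p['pair'][1]:<13s} "
                    f"diff = {p['diff']:7.2f} ms, r = {p['r']}, "
                    f"q = {p['q_stat']:.2f} (crit {p['q_crit']:.2f})"
                )
    f = d["facilitation"]
    a = f["anova"]
    lines += [
        "",
        "Multisensory facilitation (looming vs unisensory tactile):",
        f"  multisensory M = {f['multisensory_mean_ms']:.2f} ms (SE {f['multisensory_se_ms']:.2f}), "
        f"unisensory M = {f['unisensory_mean_ms']:.2f} ms (SE {f['unisensory_se_ms']:.2f})",
        f"  F({a['df_num']},{a['df_den']}) = {a['F']:.2f}, p = {a['p']:.4f}, eta_p2 = {a['eta_p2']:.2f}",
        "",
        "Exclusions: " + ", ".join(f"{k} = {v}" for k, v in sorted(d["exclusions"].items())),
        f"Provenance: config {d['provenance']['config_hash'][:12]}..., seed {d['provenance']['seed']}, "
        f"ppsbound {d['provenance']['package_version']}",
    ]
    return "\n".join(lines) + "\n"
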