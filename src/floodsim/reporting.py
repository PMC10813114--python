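"""Summary metrics across replicate runs and result file output.

Standard errors are computed across runs, never across citizens: citizens
within a run share the same event draws and are therefore correlated, so the
run is the independent sampling unit.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .config import Config
from .engine import SummaryResult

#: Fixed column order of ``summary.csv``.
SUMMARY_COLUMNS = [
    "profile", "policy", "scenario", "n_runs", "n_citizens",
    "capital_mean", "capital_se",
    "avoided_mean", "avoided_se",
    "sum_mean", "sum_se",
    "follow_pct_mean", "follow_pct_se",
    "success_medium_pct_mean", "success_medium_pct_se",
    "cice_pct_mean", "cice_pct_se",
    "authority_capital_mean", "authority_capital_se",
    "trust_authority_mean", "trust_personal_mean", "trust_social_mean",
]

EVENT_COLUMNS = [
    "run", "event", "quadrant", "severity", "indicated",
    "n_none", "n_medium", "n_maximal", "damage", "fines", "incentives",
]


def _mean_se(values) -> tuple[float, float]:
    values = [v for v in values if not (isinstance(v, float) and math.isnan(v))]
    n = len(values)
    if n == 0:
        return float("nan"), float("nan")
    mean = sum(values) / n
    if n == 1:
        return mean, float("nan")
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def summarize(result: SummaryResult) -> pd.DataFrame:
    """One row per profile: run-level means and standard errors of every
    output dimension, plus the authority's capital and mean source trust.

    The ``sum`` column is capital plus avoided damage, computed per run so the
    identity ``sum = capital + avoided`` holds exactly row by row.
    """
    cfg = result.config
    runs = result.runs
    profiles = sorted({p for r in runs for p in r.profile_stats})
    auth_mean, auth_se = _mean_se([r.authority["capital"] for r in runs])
    rows = []
    for profile in profiles:
        per_run = [r.profile_stats[profile] for r in runs if profile in r.profile_stats]
        row: dict = {
            "profile": profile,
            "policy": cfg.policy,
            "scenario": cfg.scenario,
            "n_runs": len(runs),
            "n_citizens": per_run[0]["n"],
        }
        for src_key, out_key in (
            ("capital", "capital"), ("avoided", "avoided"),
            ("capital_plus_avoided", "sum"),
            ("follow_pct", "follow_pct"),
            ("success_medium_pct", "success_medium_pct"),
            ("cice_pct", "cice_pct"),
        ):
            mean, se = _mean_se([s[src_key] for s in per_run])
            row[f"{out_key}_mean"], row[f"{out_key}_se"] = mean, se
        row["authority_capital_mean"] = auth_mean
        row["authority_capital_se"] = auth_se
        for kind in ("authority", "personal", "social"):
            vals = [r.mean_trust.get(kind) for r in runs if r.mean_trust]
            row[f"trust_{kind}_mean"] = (
                sum(vals) / len(vals) if vals else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def events_frame(result: SummaryResult) -> pd.DataFrame:
    """Per-run, per-event, per-quadrant log as a DataFrame."""
    rows = []
    for run_idx, r in enumerate(result.runs):
        for rec in r.event_rows:
            rows.append({"run": run_idx, **rec})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_outputs(table: pd.DataFrame, result: SummaryResult, out_dir) -> dict[str, Path]:
    """Write ``summary.csv``, ``events.csv``, ``config.resolved.yaml`` and a
    ``summary.json`` mirror; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["summary"] = out / "summary.csv"
    table.to_csv(paths["summary"], index=False)

    paths["events"] = out / "events.csv"
    events_frame(result).to_csv(paths["events"], index=False)

    paths["config"] = out / "config.resolved.yaml"
    result.config.save(paths["config"])

    paths["json"] = out / "summary.json"
    paths["json"].write_text(json.dumps(table.to_dict(orient="records"), indent=2))
    return paths


def preset_config(scenario: str, policy: str, profile: str = "esc",
                  free_rider_fraction: float = 0.0) -> Config:
    """A ready-made experiment configuration on the reference defaults."""
    from .config import default_config

    cfg = default_config()
    cfg.policy = policy
    if scenario == "scenario1":
        cfg.scenario = "independent"
        cfg.profile_mix = {profile: 1.0}
    elif scenario == "scenario2":
        cfg.scenario = "interdependent"
        if free_rider_fraction > 0:
            cfg.profile_mix = {"esc": 1.0 - free_rider_fraction,
                               "free_rider": free_rider_fraction}
        else:
            cfg.profile_mix = {"esc": 1.0}
    else:
        raise ValueError(f"unknown preset scenario {scenario!r}")
    return cfg
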