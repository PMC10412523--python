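"""End-to-end pipeline: sessions in, coded outcomes and report out.

Order of operations per cohort:

1. load (or synthesise) the per-participant session logs;
2. extract fixations (I-DT) and, per change, the eight-bin AOI dwell
   time-course;
3. first-pass press matching under a generous 10 s window to harvest
   reaction times, derive the cohort cutoff (mean + 3 SD) and re-match;
4. code each change: detected / RT, gaze category, LBFTS flag;
5. build the summary tables (detection, LBFTS, temporal proximity,
   learning, driving) and the inferential layer;
6. render the report and CSV bundle.

Every exclusion decision (press outside the window, false alarm) is logged
with its record id through the module logger; the run is deterministic for
a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import coding, metrics, stats
from .coding import CutoffResult, TrialOutcome
from .gaze import detect_fixations, event_timecourse
from .metrics import LbftsConfig
from .model import GROUP_ORDERS, SessionLog
from .session_io import read_cohort
from .simulate import DriverParams, default_params, simulate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "ConfigError", "run_pipeline", "process_sessions"]

log = logging.getLogger("cbdrive")


class ConfigError(ValueError):
    """The pipeline configuration is internally inconsistent."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one document.

    Either ``cohort_dir`` names a directory of recorded sessions, or a
    synthetic cohort of ``n_participants`` is generated from ``seed``.
    """

    # input
    cohort_dir: str | None = None
    n_participants: int = 12
    seed: int = 0
    include_gaze: bool = True
    # fixation extraction
    dispersion_deg: float = 1.0
    min_fix_dur_s: float = 0.100
    max_fix_dur_s: float = 0.500
    split_long_fixations: bool = True
    # response coding
    cutoff_mode: str = "derive"  # derive | fixed | paper_default
    fixed_cutoff_s: float | None = None
    first_pass_window_s: float = coding.FIRST_PASS_WINDOW_S
    # LBFTS / gaze categories
    lbfts_pre_s: float = 4.0
    lbfts_post_s: float = 4.0
    lbfts_min_dwell_ms: float = 100.0
    lbfts_denominator: str = "both_gazers"  # or all_changes

    def validate(self) -> None:
        if self.cutoff_mode not in ("derive", "fixed", "paper_default"):
            raise ConfigError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.cutoff_mode == "fixed" and self.fixed_cutoff_s is None:
            raise ConfigError("cutoff_mode='fixed' requires fixed_cutoff_s")
        if not 0.5 <= self.dispersion_deg <= 5.0:
            raise ConfigError("dispersion_deg outside the sensible 0.5-5 degree range")
        if self.lbfts_denominator not in ("both_gazers", "all_changes"):
            raise ConfigError(f"unknown lbfts_denominator {self.lbfts_denominator!r}")
        LbftsConfig(self.lbfts_pre_s, self.lbfts_post_s, self.lbfts_min_dwell_ms)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one cohort."""

    outcomes: pd.DataFrame
    cutoff: CutoffResult
    false_alarms: pd.DataFrame
    detection_by_type_complexity: pd.DataFrame
    detection_by_complexity: pd.DataFrame
    lbfts: pd.DataFrame
    lbfts_all_changes: pd.DataFrame
    temporal_proximity: pd.DataFrame
    learning: pd.DataFrame
    driving: pd.DataFrame
    timecourse_mean: pd.DataFrame
    stat_results: dict[str, stats.StatResult]
    roc: dict[str, dict[str, float]]
    meta: dict

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.outcomes.drop(columns=[], errors="ignore").to_csv(out / "outcomes.csv", index=False)
        self.false_alarms.to_csv(out / "false_alarms.csv", index=False)
        self.detection_by_type_complexity.to_csv(out / "detection_by_type_complexity.csv", index=False)
        self.detection_by_complexity.to_csv(out / "detection_by_complexity.csv", index=False)
        self.lbfts.to_csv(out / "lbfts_both_gazers.csv", index=False)
        self.lbfts_all_changes.to_csv(out / "lbfts_all_changes.csv", index=False)
        self.temporal_proximity.drop(columns=["participant_rates_pct"]).to_csv(
            out / "temporal_proximity.csv", index=False
        )
        keep = [c for c in self.learning.columns if not c.endswith("s_pct") and not c.endswith("s_ms")]
        self.learning[keep].to_csv(out / "learning_effect.csv", index=False)
        self.driving.to_csv(out / "driving_metrics.csv", index=False)
        self.timecourse_mean.to_csv(out / "timecourse_mean.csv", index=False)
        (out / "metadata.json").write_text(json.dumps(self.meta, indent=1))
        (out / "report.md").write_text(render_report(self))
        return out


def _load_or_simulate(config: PipelineConfig) -> list[SessionLog]:
    if config.cohort_dir is not None:
        log.info("reading cohort from %s", config.cohort_dir)
        return read_cohort(config.cohort_dir)
    log.info("simulating cohort: n=%d seed=%d", config.n_participants, config.seed)
    return simulate_cohort(
        config.n_participants,
        default_params(),
        seed=config.seed,
        include_gaze=config.include_gaze,
    )


def process_sessions(sessions: Sequence[SessionLog], config: PipelineConfig) -> PipelineResult:
    """Run coding + analysis on already-loaded sessions."""
    config.validate()
    lbcfg = LbftsConfig(config.lbfts_pre_s, config.lbfts_post_s, config.lbfts_min_dwell_ms)

    # fixations + first-pass RTs
    per_session_fix = []
    first_pass_rts: list[float] = []
    raw_rts: list[np.ndarray] = []
    for s in sessions:
        fixations = (
            detect_fixations(
                s.gaze,
                dispersion_deg=config.dispersion_deg,
                min_dur_s=config.min_fix_dur_s,
                max_dur_s=config.max_fix_dur_s,
                split_long=config.split_long_fixations,
            )
            if len(s.gaze)
            else []
        )
        per_session_fix.append(fixations)
        outcomes1, _ = coding.match_presses(s.events, s.presses, config.first_pass_window_s)
        first_pass_rts.extend(o.rt_s for o in outcomes1 if o.rt_s is not None)
        raw_rts.append(coding.raw_press_rts(s.events, s.presses))

    all_press_rts = np.concatenate(raw_rts) if raw_rts else np.empty(0)
    mode = {"derive": "derived", "fixed": "fixed", "paper_default": "paper_default"}[
        config.cutoff_mode
    ]
    cutoff = coding.derive_rt_cutoff(
        matched_rts=first_pass_rts if mode == "derived" else None,
        mode=mode,
        fixed_cutoff_s=config.fixed_cutoff_s,
        all_press_rts=all_press_rts,
    )
    log.info(
        "RT cutoff %.3f s (%s, %d RTs); %.1f%% of presses inside the window",
        cutoff.cutoff_s, cutoff.mode, cutoff.n_rts_used, cutoff.inside_fraction,
    )

    # final matching + gaze coding
    all_outcomes: list[TrialOutcome] = []
    fa_rows = []
    drive_rows = []
    for s, fixations in zip(sessions, per_session_fix):
        outcomes, false_alarms = coding.match_presses(s.events, s.presses, cutoff.cutoff_s)
        order = {level: k for k, level in enumerate(GROUP_ORDERS[s.group])}
        ev_by_id = {e.change_id: e for e in s.events}
        for o in outcomes:
            o.participant_id = s.participant_id
            o.segment_order = order[o.complexity]
            if len(s.gaze) and fixations is not None:
                e = ev_by_id[o.change_id]
                near = [
                    f
                    for f in fixations
                    if f.end_t > e.trigger_t - 4.0 and f.start_t < e.trigger_t + 4.0
                ]
                tc = event_timecourse(near, s.gaze, e, s.aois[e.aoi_id])
                o.timecourse = tc
                pre, post = tc.dwell_window_ms(lbcfg.pre_window_s, lbcfg.post_window_s)
                o.dwell_pre_ms, o.dwell_post_ms = pre, post
                o.gaze_category = metrics.gaze_category(pre, post, lbcfg.min_dwell_ms)
                o.lbfts = metrics.classify_lbfts(o, lbcfg)
            else:
                o.gaze_category = None
                o.lbfts = None
        all_outcomes.extend(outcomes)
        for p in false_alarms:
            log.debug("false alarm: %s press at %.3f s (%s)", p.side, p.t, s.participant_id)
            fa_rows.append({"participant_id": s.participant_id, "t": p.t, "side": p.side})
        for level, dm in metrics.driving_metrics(s.driving, s.segment_bounds).items():
            drive_rows.append(
                {
                    "participant_id": s.participant_id,
                    "complexity": level,
                    "avg_speed_kmh": dm.avg_speed_kmh,
                    "completion_min": dm.completion_min,
                    "brake_hits": dm.brake_hits,
                }
            )

    df = coding.outcomes_frame(all_outcomes)
    have_gaze = df["gaze_category"].notna().any()

    det_tc = coding.detection_table(df, ["change_type", "complexity"])
    det_c = coding.detection_table(df, ["complexity"])
    lb = metrics.lbfts_table(df, "both_gazers") if have_gaze else pd.DataFrame()
    lb_all = metrics.lbfts_table(df, "all_changes") if have_gaze else pd.DataFrame()
    prox = metrics.temporal_proximity_table(df)
    learning = metrics.learning_effect(df)
    driving = pd.DataFrame(drive_rows)

    # mean dwell time-course per change type x detection outcome
    tc_rows = []
    for o in all_outcomes:
        if o.timecourse is None:
            continue
        tc_rows.append(
            {
                "change_type": o.change_type,
                "detected": o.detected,
                **{f"bin_{k}": o.timecourse.bins_ms[k] for k in range(8)},
            }
        )
    if tc_rows:
        timecourse_mean = (
            pd.DataFrame(tc_rows).groupby(["change_type", "detected"], observed=True).mean().reset_index()
        )
    else:
        timecourse_mean = pd.DataFrame()

    stat_results = _inferential(df, driving, prox, learning)
    roc = _roc_from_table(det_tc)

    meta = {
        "n_participants": int(df["participant_id"].nunique()),
        "n_changes": int(len(df)),
        "cutoff_s": cutoff.cutoff_s,
        "cutoff_mode": cutoff.mode,
        "inside_fraction_pct": cutoff.inside_fraction,
        "outside_fraction_pct": cutoff.outside_fraction,
        "config": dataclasses.asdict(config),
    }
    return PipelineResult(
        outcomes=df,
        cutoff=cutoff,
        false_alarms=pd.DataFrame(fa_rows, columns=["participant_id", "t", "side"]),
        detection_by_type_complexity=det_tc,
        detection_by_complexity=det_c,
        lbfts=lb,
        lbfts_all_changes=lb_all,
        temporal_proximity=prox,
        learning=learning,
        driving=driving,
        timecourse_mean=timecourse_mean,
        stat_results=stat_results,
        roc=roc,
        meta=meta,
    )


def _roc_from_table(det_tc: pd.DataFrame) -> dict[str, dict[str, float]]:
    out = {}
    for ct, sub in det_tc.groupby("change_type", observed=True):
        rates = {row["complexity"]: row["rate_pct"] for _, row in sub.iterrows()}
        if set(rates) == {"low", "medium", "high"}:
            out[ct] = metrics.roc_slopes(rates)
    return out


def _inferential(
    df: pd.DataFrame,
    driving: pd.DataFrame,
    prox: pd.DataFrame,
    learning: pd.DataFrame,
) -> dict[str, stats.StatResult]:
    """Participant-level inferential battery (cell means as observations)."""
    out: dict[str, stats.StatResult] = {}
    cell = (
        df.groupby(["participant_id", "complexity", "change_type"], observed=True)["detected"]
        .mean()
        .mul(100.0)
        .reset_index(name="rate_pct")
    )
    try:
        fact = stats.anova_factorial(
            cell["rate_pct"], cell["complexity"], cell["change_type"]
        )
        out["detection_complexity"] = fact["factor_a"]
        out["detection_change_type"] = fact["factor_b"]
        out["detection_interaction"] = fact["interaction"]
    except ValueError as err:
        log.warning("factorial ANOVA skipped: %s", err)

    for level in ("low", "medium", "high"):
        sub = cell[cell["complexity"] == level].pivot(
            index="participant_id", columns="change_type", values="rate_pct"
        )
        if {"behaviour_relevant", "behaviour_irrelevant"} <= set(sub.columns):
            both = sub[["behaviour_relevant", "behaviour_irrelevant"]].dropna()
            if len(both) >= 2:
                try:
                    out[f"paired_relevant_vs_irrelevant_{level}"] = stats.paired_t(
                        both["behaviour_relevant"], both["behaviour_irrelevant"]
                    )
                except ValueError as err:
                    log.warning("paired t (%s) skipped: %s", level, err)

    gap_groups = [
        r["participant_rates_pct"] for _, r in prox.iterrows() if len(r["participant_rates_pct"]) >= 2
    ]
    if len(gap_groups) >= 2:
        out["temporal_proximity"] = stats.anova_oneway(gap_groups)

    if not driving.empty:
        for col, label in (("brake_hits", "brake_hits"), ("completion_min", "completion")):
            groups = [
                sub[col].to_numpy()
                for _, sub in driving.groupby("complexity", observed=True)
                if len(sub) >= 2
            ]
            if len(groups) >= 2:
                out[f"driving_{label}"] = stats.anova_oneway(groups)

    for _, row in learning.iterrows():
        first, last = row["first_rates_pct"], row["last_rates_pct"]
        if len(first) >= 2:
            try:
                out[f"learning_detection_{row['change_type']}"] = stats.paired_t(last, first)
            except ValueError as err:
                log.warning("learning paired t (%s) skipped: %s", row["change_type"], err)
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Full run: load or simulate a cohort, process, optionally save."""
    config.validate()
    sessions = _load_or_simulate(config)
    result = process_sessions(sessions, config)
    if out_dir is not None:
        result.save(out_dir)
    return result


def render_report(result: PipelineResult) -> str:
    """Human-readable markdown summary of one pipeline run."""
    m = result.meta
    lines = [
        "# Change-detection-while-driving report",
        "",
        f"Cohort: {m['n_participants']} participants, {m['n_changes']} coded changes.",
        f"RT cutoff: {m['cutoff_s']:.3f} s ({m['cutoff_mode']}); "
        f"{m['inside_fraction_pct']:.1f}% of presses inside the legitimate window, "
        f"{m['outside_fraction_pct']:.1f}% outside.",
        "",
        "## Detection rate (%) by change type and complexity",
        "",
        result.detection_by_type_complexity.to_string(index=False),
        "",
        "## Rate of change of detection across complexity (percentage points)",
        "",
    ]
    for ct, sl in result.roc.items():
        lines.append(
            f"- {ct}: low->medium {sl['low_to_medium']:+.1f}, "
            f"medium->high {sl['medium_to_high']:+.1f} (mean {sl['mean']:+.1f})"
        )
    if not result.lbfts.empty:
        lines += [
            "",
            "## LBFTS errors (denominator: both-window gazers)",
            "",
            result.lbfts.to_string(index=False),
        ]
    lines += [
        "",
        "## Property-change detection by temporal proximity",
        "",
        result.temporal_proximity.drop(columns=["participant_rates_pct"]).to_string(index=False),
        "",
        "## Driving metrics (cohort means)",
        "",
    ]
    if not result.driving.empty:
        dm = (
            result.driving.groupby("complexity", observed=True)[
                ["avg_speed_kmh", "completion_min", "brake_hits"]
            ]
            .mean()
            .reset_index()
        )
        lines.append(dm.to_string(index=False))
    lines += ["", "## Statistics", ""]
    for name, res in result.stat_results.items():
        lines.append(f"- {name}: {res}")
    lines.append("")
    return "\n".join(lines)
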