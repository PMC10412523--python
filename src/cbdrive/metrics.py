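"""Derived analyses: gaze categories, LBFTS errors, detection-rate slopes,
driving metrics, temporal proximity and the learning-effect comparison.

A "looked-but-failed-to-see" (LBFTS) error is a missed change for which the
participant nonetheless dwelt on the change's AOI for more than
``min_dwell_ms`` (default 100 ms) in both the pre-change and post-change
windows (defaults 4 s each; a 2 s pre-window is the standard robustness
variant). Gaze categories partition every coded change into before_only /
after_only / both / none by the same dwell threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import TrialOutcome
from .model import COMPLEXITY_LEVELS, GAP_LEVELS_S, DrivingStream, ValidationError

__all__ = [
    "LbftsConfig",
    "DrivingMetrics",
    "gaze_category",
    "classify_lbfts",
    "lbfts_table",
    "roc_slopes",
    "driving_metrics",
    "temporal_proximity_table",
    "learning_effect",
]


@dataclass(frozen=True)
class LbftsConfig:
    """Windows and dwell threshold for the LBFTS / gaze-category coding."""

    pre_window_s: float = 4.0
    post_window_s: float = 4.0
    min_dwell_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.pre_window_s <= 0 or self.post_window_s <= 0 or self.min_dwell_ms <= 0:
            raise ValueError("LbftsConfig values must be positive")
        if self.min_dwell_ms > 1000.0 * min(self.pre_window_s, self.post_window_s):
            raise ValueError("min_dwell_ms cannot exceed the shorter window")


@dataclass(frozen=True)
class DrivingMetrics:
    """Per-complexity driving summary for one participant."""

    complexity: str
    avg_speed_kmh: float
    completion_min: float
    brake_hits: int


def gaze_category(
    dwell_pre_ms: float, dwell_post_ms: float, min_dwell_ms: float = 100.0
) -> str:
    """Classify AOI dwell into both / before_only / after_only / none.

    A window counts as gazed when its dwell reaches ``min_dwell_ms``.
    """
    if dwell_pre_ms < 0 or dwell_post_ms < 0:
        raise ValueError("dwell must be non-negative")
    pre = dwell_pre_ms >= min_dwell_ms
    post = dwell_post_ms >= min_dwell_ms
    if pre and post:
        return "both"
    if pre:
        return "before_only"
    if post:
        return "after_only"
    return "none"


def classify_lbfts(outcome: TrialOutcome, config: LbftsConfig = LbftsConfig()) -> bool:
    """True iff the change was missed yet gazed in both configured windows.

    When the outcome carries a dwell time-course, the windows are recomputed
    from it under ``config``; otherwise the stored window totals are used.
    """
    if outcome.detected:
        return False
    if outcome.timecourse is not None:
        pre, post = outcome.timecourse.dwell_window_ms(config.pre_window_s, config.post_window_s)
    else:
        if outcome.dwell_pre_ms is None or outcome.dwell_post_ms is None:
            raise ValueError(f"outcome {outcome.change_id} has no dwell information")
        pre, post = outcome.dwell_pre_ms, outcome.dwell_post_ms
    return gaze_category(pre, post, config.min_dwell_ms) == "both"


def lbfts_table(
    outcomes: pd.DataFrame,
    denominator: str = "both_gazers",
) -> pd.DataFrame:
    """LBFTS rate per change_type x complexity cell.

    ``denominator`` is ``both_gazers`` (changes gazed in both windows, the
    reading suggested by the study's per-gaze normalisation) or
    ``all_changes``. Cells with an empty denominator are absent.
    """
    if denominator not in ("both_gazers", "all_changes"):
        raise ValueError("denominator must be both_gazers or all_changes")
    df = outcomes.copy()
    df["lbfts"] = df["lbfts"].astype(bool)
    rows = []
    for (ct, cx), cell in df.groupby(["change_type", "complexity"], observed=True):
        n_lbfts = int(cell["lbfts"].sum())
        if denominator == "both_gazers":
            denom = int((cell["gaze_category"] == "both").sum())
        else:
            denom = len(cell)
        if denom == 0:
            continue
        rows.append(
            {
                "change_type": ct,
                "complexity": cx,
                "n_lbfts": n_lbfts,
                "denominator": denom,
                "rate_pct": 100.0 * n_lbfts / denom,
            }
        )
    return pd.DataFrame(rows)


def roc_slopes(
    rates_by_complexity: Sequence[float] | dict[str, float],
    mode: str = "difference",
) -> dict[str, float]:
    """Rate-of-change of detection performance across complexity levels.

    Takes rates (percent) for the ordered levels low, medium, high; returns
    the low-to-medium and medium-to-high slopes and their mean. The default
    ``difference`` mode is percentage-point subtraction (medium - low,
    high - medium); ``ratio`` gives percentage change relative to the lower
    level.
    """
    if isinstance(rates_by_complexity, dict):
        try:
            rates = [rates_by_complexity[c] for c in COMPLEXITY_LEVELS]
        except KeyError as e:
            raise ValueError(f"missing complexity level {e.args[0]!r}") from None
    else:
        rates = list(rates_by_complexity)
        if len(rates) != 3:
            raise ValueError("need rates for exactly low, medium, high")
    low, med, high = (float(r) for r in rates)
    if mode == "difference":
        s1, s2 = med - low, high - med
    elif mode == "ratio":
        if low == 0 or med == 0:
            raise ValueError("ratio mode needs non-zero base rates")
        s1, s2 = 100.0 * (med - low) / low, 100.0 * (high - med) / med
    else:
        raise ValueError("mode must be difference or ratio")
    return {"low_to_medium": s1, "medium_to_high": s2, "mean": 0.5 * (s1 + s2)}


def driving_metrics(
    driving: DrivingStream,
    segment_bounds: dict[str, tuple[float, float]],
) -> dict[str, DrivingMetrics]:
    """Average speed, completion time and brake hits per complexity segment.

    Average speed is the time-weighted mean of the speed samples inside the
    segment; a brake hit is a rising edge (False -> True) of the pedal
    signal. Segments without samples are absent from the result.
    """
    out: dict[str, DrivingMetrics] = {}
    for level, (a, b) in segment_bounds.items():
        sel = (driving.t >= a) & (driving.t < b)
        if not sel.any():
            continue
        t = driving.t[sel]
        speed = driving.speed_kmh[sel]
        brake = driving.brake[sel].astype(int)
        if t.size >= 2:
            w = np.diff(t)
            avg_speed = float(np.sum(0.5 * (speed[1:] + speed[:-1]) * w) / np.sum(w))
        else:
            avg_speed = float(speed[0])
        rising = int(np.sum(np.diff(brake) == 1)) + int(brake[0] == 1)
        out[level] = DrivingMetrics(
            complexity=level,
            avg_speed_kmh=avg_speed,
            completion_min=(b - a) / 60.0,
            brake_hits=rising,
        )
    return out


def temporal_proximity_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Property-change detection rate by temporal-proximity gap level.

    Returns exactly six rows (gaps 0, 1, 2, 4, 6, 8 s) with the pooled rate
    and per-participant mean rates (the unit fed to the one-way ANOVA).
    """
    props = outcomes[outcomes["change_type"] == "property"]
    bad = set(props["gap_s"].unique()) - set(GAP_LEVELS_S)
    if bad:
        raise ValidationError(f"unknown gap levels in outcomes: {sorted(bad)}")
    rows = []
    for gap in GAP_LEVELS_S:
        cell = props[props["gap_s"] == gap]
        per_part = cell.groupby("participant_id", observed=True)["detected"].mean() * 100.0
        rows.append(
            {
                "gap_s": gap,
                "n": len(cell),
                "rate_pct": 100.0 * cell["detected"].mean() if len(cell) else np.nan,
                "participant_rates_pct": per_part.to_list(),
            }
        )
    return pd.DataFrame(rows)


def learning_effect(outcomes: pd.DataFrame) -> pd.DataFrame:
    """First-block vs last-block comparison per change type.

    The session's three complexity blocks are taken as its "sessions"; for
    each change type the detection rate and mean AOI dwell in the first
    block are compared with the third. Returns per-participant paired
    values (the input to a paired t-test) plus pooled summaries.
    """
    if outcomes["segment_order"].isna().any():
        raise ValidationError("learning_effect needs segment_order on every outcome")
    if set(outcomes["segment_order"].unique()) != {0, 1, 2}:
        raise ValidationError("learning_effect needs all three complexity blocks")
    df = outcomes.copy()
    df["dwell_total_ms"] = df["dwell_pre_ms"].fillna(0.0) + df["dwell_post_ms"].fillna(0.0)
    rows = []
    for ct, sub in df.groupby("change_type", observed=True):
        first = sub[sub["segment_order"] == 0]
        last = sub[sub["segment_order"] == 2]
        f_rate = first.groupby("participant_id", observed=True)["detected"].mean() * 100.0
        l_rate = last.groupby("participant_id", observed=True)["detected"].mean() * 100.0
        f_dwell = first.groupby("participant_id", observed=True)["dwell_total_ms"].mean()
        l_dwell = last.groupby("participant_id", observed=True)["dwell_total_ms"].mean()
        common = sorted(set(f_rate.index) & set(l_rate.index))
        rows.append(
            {
                "change_type": ct,
                "n_participants": len(common),
                "first_rate_pct": float(f_rate[common].mean()),
                "last_rate_pct": float(l_rate[common].mean()),
                "first_rates_pct": f_rate[common].to_list(),
                "last_rates_pct": l_rate[common].to_list(),
                "first_dwell_ms": float(f_dwell[common].mean()),
                "last_dwell_ms": float(l_dwell[common].mean()),
                "first_dwells_ms": f_dwell[common].to_list(),
                "last_dwells_ms": l_dwell[common].to_list(),
            }
        )
    return pd.DataFrame(rows)
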