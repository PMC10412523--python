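"""Response coding: from raw button presses to validated detections.

A press counts as a successful detection of a change when

* (C1) its side matches the change (right for behaviour changes, left for
  property changes), and
* (C2) it occurs before the next change requiring the same side, and
* it falls inside the legitimate reaction-time window
  ``[trigger, trigger + cutoff)``.

The cutoff is the cohort-pooled mean reaction time plus three sample
standard deviations (the study's derived value is 4.1 s, available as
``paper_default`` mode without data). C2 is applied per button side so that
0 s-gap pairs — where a behaviour and a property change trigger
simultaneously — remain separable through the two buttons.

Attribution is deterministic: presses are scanned in time order; a press
can qualify for at most one change (the latest same-side change that
precedes it), the earliest qualifying press wins a change, and every press
ends up either attributed or in the false-alarm list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze import DwellTimecourse
from .model import ButtonPress, ChangeEvent

__all__ = [
    "PAPER_DEFAULT_CUTOFF_S",
    "CutoffResult",
    "TrialOutcome",
    "derive_rt_cutoff",
    "raw_press_rts",
    "match_presses",
    "outcomes_frame",
    "detection_table",
]

PAPER_DEFAULT_CUTOFF_S = 4.1
#: Generous first-pass window used to harvest RTs before the cutoff exists.
FIRST_PASS_WINDOW_S = 10.0


@dataclass(frozen=True)
class CutoffResult:
    """Derived reaction-time cutoff plus the inside/outside-window audit."""

    cutoff_s: float
    mode: str  # derived | fixed | paper_default
    n_rts_used: int
    inside_fraction: float  # % of presses inside the legitimate window
    outside_fraction: float

    def __post_init__(self) -> None:
        if self.cutoff_s <= 0:
            raise ValueError("cutoff_s must be positive")


@dataclass
class TrialOutcome:
    """Per-change coded result; gaze fields are filled by the pipeline."""

    change_id: str
    change_type: str
    complexity: str
    gap_s: float
    encounter_index: int
    pair_id: str
    detected: bool
    rt_s: float | None = None
    press_index: int | None = None
    participant_id: str = ""
    segment_order: int | None = None  # 0,1,2: which block the change sat in
    gaze_category: str | None = None  # before_only | after_only | both | none
    dwell_pre_ms: float | None = None
    dwell_post_ms: float | None = None
    lbfts: bool | None = None
    timecourse: DwellTimecourse | None = None


def derive_rt_cutoff(
    matched_rts: Sequence[float] | np.ndarray | None = None,
    mode: str = "derived",
    fixed_cutoff_s: float | None = None,
    all_press_rts: Sequence[float] | np.ndarray | None = None,
) -> CutoffResult:
    """Reaction-time cutoff: pooled mean RT + 3 sample standard deviations.

    Parameters
    ----------
    matched_rts : reaction times of first-pass matched presses, pooled
        across the whole cohort (needed for ``derived`` mode; >= 2 values).
    mode : ``derived`` (mean + 3 SD, n-1 denominator), ``fixed`` (use
        ``fixed_cutoff_s``) or ``paper_default`` (4.1 s, no data needed).
    all_press_rts : raw per-press RTs relative to the latest same-side
        change (NaN when no change precedes); when given, the
        inside/outside audit re-screens these against the cutoff. Falls
        back to ``matched_rts``.

    The audit is exactly complementary: inside + outside = 100.
    """
    if mode == "paper_default":
        cutoff = PAPER_DEFAULT_CUTOFF_S
        n_used = 0
    elif mode == "fixed":
        if fixed_cutoff_s is None:
            raise ValueError("mode='fixed' requires fixed_cutoff_s")
        cutoff = float(fixed_cutoff_s)
        n_used = 0
    elif mode == "derived":
        rts = np.asarray(matched_rts, dtype=float) if matched_rts is not None else np.empty(0)
        if rts.size < 2:
            raise ValueError("derived cutoff needs at least 2 matched reaction times")
        cutoff = float(rts.mean() + 3.0 * rts.std(ddof=1))
        n_used = int(rts.size)
    else:
        raise ValueError(f"unknown cutoff mode {mode!r}")

    screen = all_press_rts if all_press_rts is not None else matched_rts
    screen = np.asarray(screen, dtype=float) if screen is not None else np.empty(0)
    if screen.size:
        inside = 100.0 * float(np.sum((screen >= 0) & (screen < cutoff))) / screen.size
    else:
        inside = 100.0
    return CutoffResult(
        cutoff_s=cutoff,
        mode=mode,
        n_rts_used=n_used,
        inside_fraction=inside,
        outside_fraction=100.0 - inside,
    )


def raw_press_rts(events: Sequence[ChangeEvent], presses: Sequence[ButtonPress]) -> np.ndarray:
    """Per-press RT relative to the latest preceding same-side change.

    NaN where no same-side change precedes the press. This is the quantity
    re-screened against the cutoff for the inside/outside-window audit.
    """
    out = np.full(len(presses), np.nan)
    by_side = {
        side: sorted(t for e in events if e.required_side == side for t in [e.trigger_t])
        for side in ("left", "right")
    }
    for i, p in enumerate(presses):
        ts = by_side[p.side]
        k = int(np.searchsorted(ts, p.t, side="right")) - 1
        if k >= 0:
            out[i] = p.t - ts[k]
    return out


def match_presses(
    events: Sequence[ChangeEvent],
    presses: Sequence[ButtonPress],
    cutoff_s: float,
) -> tuple[list[TrialOutcome], list[ButtonPress]]:
    """Attribute presses to changes under C1 + C2 and the RT cutoff.

    Returns one outcome per change (in encounter order) and the list of
    unattributed presses (false alarms). Every press is exactly one of
    attributed or false alarm.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be positive")
    ordered = sorted(events, key=lambda e: (e.trigger_t, 0 if e.is_behaviour else 1))
    by_side: dict[str, list[int]] = {"left": [], "right": []}
    for idx, e in enumerate(ordered):
        by_side[e.required_side].append(idx)

    assigned: dict[int, tuple[float, int]] = {}  # event idx -> (rt, press idx)
    false_alarms: list[ButtonPress] = []
    for p_idx, p in enumerate(sorted(presses, key=lambda p: p.t)):
        side_idx = by_side[p.side]
        trig = [ordered[k].trigger_t for k in side_idx]
        pos = int(np.searchsorted(trig, p.t, side="right")) - 1
        cand = side_idx[pos] if pos >= 0 else None
        if cand is not None and cand not in assigned:
            rt = p.t - ordered[cand].trigger_t
            if 0.0 <= rt < cutoff_s:
                assigned[cand] = (rt, p_idx)
                continue
        false_alarms.append(p)

    outcomes = []
    for idx, e in enumerate(ordered):
        hit = assigned.get(idx)
        outcomes.append(
            TrialOutcome(
                change_id=e.change_id,
                change_type=e.change_type,
                complexity=e.complexity,
                gap_s=e.gap_s,
                encounter_index=e.encounter_index,
                pair_id=e.pair_id,
                detected=hit is not None,
                rt_s=hit[0] if hit else None,
                press_index=hit[1] if hit else None,
            )
        )
    return outcomes, false_alarms


def outcomes_frame(outcomes: Sequence[TrialOutcome]) -> pd.DataFrame:
    """Flatten outcomes (possibly many participants) into a DataFrame."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "participant_id": o.participant_id,
                "change_id": o.change_id,
                "pair_id": o.pair_id,
                "change_type": o.change_type,
                "complexity": o.complexity,
                "gap_s": o.gap_s,
                "encounter_index": o.encounter_index,
                "segment_order": o.segment_order,
                "detected": bool(o.detected),
                "rt_s": np.nan if o.rt_s is None else o.rt_s,
                "gaze_category": o.gaze_category,
                "dwell_pre_ms": np.nan if o.dwell_pre_ms is None else o.dwell_pre_ms,
                "dwell_post_ms": np.nan if o.dwell_post_ms is None else o.dwell_post_ms,
                "lbfts": o.lbfts,
            }
        )
    return pd.DataFrame(rows)


def detection_table(outcomes: pd.DataFrame, group_by: Sequence[str]) -> pd.DataFrame:
    """Detection counts and percentage per cell of ``group_by``.

    ``group_by`` is any subset of {participant_id, change_type, complexity,
    gap_s, encounter_index, segment_order}. Cells that do not occur are
    simply absent (a rate is never reported as 0/0).
    """
    if outcomes.empty:
        raise ValueError("detection_table needs at least one outcome")
    allowed = {
        "participant_id",
        "change_type",
        "complexity",
        "gap_s",
        "encounter_index",
        "segment_order",
    }
    bad = set(group_by) - allowed
    if bad:
        raise ValueError(f"unknown group_by columns: {sorted(bad)}")
    g = outcomes.groupby(list(group_by), observed=True)["detected"]
    tab = g.agg(n_detected="sum", n_total="count").reset_index()
    tab["rate_pct"] = 100.0 * tab["n_detected"] / tab["n_total"]
    return tab
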