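"""Change-event schedule builder and validator.

The study design: 72 changes in 36 pairs, 12 pairs per visuospatial
complexity level, each pair consisting of one behaviour change (relevant or
irrelevant) followed by one property change after a gap of 0, 1, 2, 4, 6 or
8 s. Complexity blocks are driven in the counterbalanced group order
(A: medium-high-low, B: high-low-medium, C: low-medium-high) and consecutive
pairs are at least 10 s apart.

Gap levels are balanced both overall (each of the 6 gaps in exactly 6 pairs)
and within each level (each gap twice per level); behaviour changes split
6 relevant + 6 irrelevant per level. Gap/type placement within a level is
randomised by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    COMPLEXITY_LEVELS,
    GAP_LEVELS_S,
    GROUP_ORDERS,
    ChangeEvent,
)

__all__ = ["ScheduleSpec", "ScheduleError", "build_schedule", "validate_schedule"]


class ScheduleError(ValueError):
    """The schedule specification is infeasible or inconsistent."""


@dataclass(frozen=True)
class ScheduleSpec:
    """Parameters of the session-level change schedule.

    ``interpair_gap_range_s`` is the uniform range the spacing between
    consecutive pairs (previous property trigger to next behaviour trigger)
    is drawn from; its lower end enforces the 10 s minimum separation.
    ``lead_in_s`` is quiet driving before the first pair of each block and
    ``tail_s`` after the last, so that AOI windows and response windows are
    always covered.
    """

    group: str = "C"
    n_pairs_per_level: int = 12
    gap_levels_s: tuple[float, ...] = GAP_LEVELS_S
    min_interpair_gap_s: float = 10.0
    interpair_gap_range_s: tuple[float, float] = (10.0, 60.0)
    relevant_pairs_per_level: int = 6
    lead_in_s: float = 12.0
    tail_s: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUP_ORDERS:
            raise ScheduleError(f"group must be one of A,B,C, got {self.group!r}")
        if self.n_pairs_per_level < 1:
            raise ScheduleError("n_pairs_per_level must be >= 1")
        n_gaps = len(self.gap_levels_s)
        if (self.n_pairs_per_level * len(COMPLEXITY_LEVELS)) % n_gaps:
            raise ScheduleError(
                f"{self.n_pairs_per_level} pairs/level x 3 levels cannot balance "
                f"{n_gaps} gap levels"
            )
        if self.n_pairs_per_level % n_gaps:
            raise ScheduleError(
                "gap levels cannot be balanced within a complexity level: "
                f"{self.n_pairs_per_level} pairs vs {n_gaps} gaps"
            )
        if not 0 <= self.relevant_pairs_per_level <= self.n_pairs_per_level:
            raise ScheduleError("relevant_pairs_per_level out of range")
        lo, hi = self.interpair_gap_range_s
        if lo < self.min_interpair_gap_s or hi < lo:
            raise ScheduleError("interpair_gap_range_s must lie above the 10 s minimum")


def build_schedule(spec: ScheduleSpec) -> tuple[list[ChangeEvent], dict[str, tuple[float, float]]]:
    """Build the 72-change schedule and the complexity segment bounds.

    Returns events in encounter order (``encounter_index`` set 0..71) and
    the half-open ``[a, b)`` segment bounds per complexity level; the three
    segments are contiguous and follow the group's block order.
    """
    rng = np.random.default_rng(spec.seed)
    order = GROUP_ORDERS[spec.group]
    per_gap = spec.n_pairs_per_level // len(spec.gap_levels_s)

    events: list[ChangeEvent] = []
    segment_bounds: dict[str, tuple[float, float]] = {}
    t = 0.0
    pair_no = 0
    for level in order:
        seg_start = t
        gaps = np.repeat(np.asarray(spec.gap_levels_s, dtype=float), per_gap)
        rng.shuffle(gaps)
        kinds = np.array(
            ["behaviour_relevant"] * spec.relevant_pairs_per_level
            + ["behaviour_irrelevant"] * (spec.n_pairs_per_level - spec.relevant_pairs_per_level)
        )
        rng.shuffle(kinds)

        t += spec.lead_in_s
        for gap, beh_kind in zip(gaps, kinds):
            if pair_no:
                t += float(rng.uniform(*spec.interpair_gap_range_s))
            pair_id = f"pair{pair_no:02d}"
            beh_t = t
            prop_t = beh_t + float(gap)
            events.append(
                ChangeEvent(
                    change_id=f"{pair_id}b",
                    pair_id=pair_id,
                    change_type=str(beh_kind),
                    complexity=level,
                    trigger_t=beh_t,
                    aoi_id=f"{pair_id}b_aoi",
                    gap_s=float(gap),
                    encounter_index=2 * pair_no,
                )
            )
            events.append(
                ChangeEvent(
                    change_id=f"{pair_id}p",
                    pair_id=pair_id,
                    change_type="property",
                    complexity=level,
                    trigger_t=prop_t,
                    aoi_id=f"{pair_id}p_aoi",
                    gap_s=float(gap),
                    encounter_index=2 * pair_no + 1,
                )
            )
            t = prop_t
            pair_no += 1
        t += spec.tail_s
        segment_bounds[level] = (seg_start, t)
    return events, segment_bounds


def validate_schedule(
    events: list[ChangeEvent],
    spec: ScheduleSpec | None = None,
) -> list[str]:
    """Check every design rule; returns a list of human-readable violations.

    An empty list means the schedule satisfies the full design. Rules are
    checked against ``spec`` (defaults if omitted) and each finding names
    the rule and the offending pair/change ids.
    """
    spec = spec or ScheduleSpec()
    v: list[str] = []
    if not events:
        return ["empty_schedule: no events"]

    n_levels = len(COMPLEXITY_LEVELS)
    expect_pairs = spec.n_pairs_per_level * n_levels
    if len(events) != 2 * expect_pairs:
        v.append(f"count: expected {2 * expect_pairs} changes, found {len(events)}")

    by_pair: dict[str, list[ChangeEvent]] = {}
    for e in events:
        by_pair.setdefault(e.pair_id, []).append(e)

    for pid, members in by_pair.items():
        beh = [e for e in members if e.is_behaviour]
        prop = [e for e in members if not e.is_behaviour]
        if len(beh) != 1 or len(prop) != 1:
            v.append(f"pair_composition: {pid} must hold one behaviour + one property change")
            continue
        b, p = beh[0], prop[0]
        if p.trigger_t < b.trigger_t:
            v.append(f"pair_order: {pid} property change precedes its behaviour change")
        elif abs((p.trigger_t - b.trigger_t) - p.gap_s) > 1e-9:
            v.append(
                f"pair_gap: {pid} spacing {p.trigger_t - b.trigger_t:.6g} s != gap_s {p.gap_s:.6g} s"
            )

    # counts per level and gap balance
    pairs = [m for m in by_pair.values() if len(m) == 2]
    level_counts: dict[str, int] = {}
    gap_counts: dict[float, int] = {}
    for members in pairs:
        level_counts[members[0].complexity] = level_counts.get(members[0].complexity, 0) + 1
        g = members[0].gap_s
        gap_counts[g] = gap_counts.get(g, 0) + 1
    for level in COMPLEXITY_LEVELS:
        if level_counts.get(level, 0) != spec.n_pairs_per_level:
            v.append(
                f"pairs_per_level: {level} has {level_counts.get(level, 0)} pairs, "
                f"expected {spec.n_pairs_per_level}"
            )
    per_gap = expect_pairs // len(spec.gap_levels_s)
    for g in spec.gap_levels_s:
        if gap_counts.get(float(g), 0) != per_gap:
            v.append(
                f"gap_balance: gap {g} s used in {gap_counts.get(float(g), 0)} pairs, "
                f"expected {per_gap}"
            )

    # inter-pair spacing: next behaviour trigger - previous property trigger
    ordered = sorted(
        (m for m in pairs),
        key=lambda m: min(e.trigger_t for e in m),
    )
    for prev, nxt in zip(ordered, ordered[1:]):
        prev_prop = max(e.trigger_t for e in prev)
        nxt_beh = min(e.trigger_t for e in nxt)
        if nxt_beh - prev_prop < spec.min_interpair_gap_s - 1e-9:
            v.append(
                f"min_interpair_gap: {prev[0].pair_id} -> {nxt[0].pair_id} spaced "
                f"{nxt_beh - prev_prop:.6g} s < {spec.min_interpair_gap_s} s"
            )

    # complexity blocks in group order
    seq = [e.complexity for e in sorted(events, key=lambda e: e.trigger_t)]
    blocks: list[str] = []
    for c in seq:
        if not blocks or blocks[-1] != c:
            blocks.append(c)
    if tuple(blocks) != GROUP_ORDERS[spec.group]:
        v.append(
            f"block_order: complexity order {blocks} does not match group "
            f"{spec.group} order {list(GROUP_ORDERS[spec.group])}"
        )
    return v
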