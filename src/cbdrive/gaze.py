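"""Fixation extraction and dynamic-AOI dwell analysis.

Fixations are identified with a spherical dispersion-threshold (I-DT)
scheme: a window of consecutive valid gaze samples is grown for as long as
the maximum pairwise angular separation of its directions stays at or below
the dispersion threshold; a maximal window lasting at least ``min_dur_s``
becomes a fixation, and windows longer than ``max_dur_s`` are split into
consecutive fixations of equal time span (so dwell time is preserved while
each emitted fixation honours the 100-500 ms duration band). Invalid
samples, and inter-sample gaps longer than ``max_sample_gap_s`` (blinks,
dropouts), break the window.

Dwell on an AOI is scored per fixation: a fixation lands on the AOI when
the angle between its centroid direction and the head-to-AOI-centre
direction (both evaluated at the fixation midpoint) is within the AOI's
angular radius ``arctan(radius / distance)``. Saccade samples never
contribute. Event-aligned time-courses apportion the landed intervals into
eight half-open 1 s bins spanning 4 s before to 4 s after the trigger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import AOI, ChangeEvent, GazeStream, ValidationError

__all__ = [
    "Fixation",
    "DwellTimecourse",
    "CoverageError",
    "angular_separation",
    "detect_fixations",
    "aoi_dwell",
    "event_timecourse",
]

DEFAULT_DISPERSION_DEG = 1.0  # midpoint of the 0.7-1.3 deg guideline band
DEFAULT_MIN_DUR_S = 0.100
DEFAULT_MAX_DUR_S = 0.500
DEFAULT_MAX_SAMPLE_GAP_S = 0.050


class CoverageError(ValueError):
    """The requested window is not covered by the AOI track or gaze stream."""


@dataclass(frozen=True)
class Fixation:
    """One fixation: time extent, mean direction and angular spread."""

    start_t: float
    end_t: float
    centroid_dir: np.ndarray
    dispersion_deg: float

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t

    @property
    def midpoint_t(self) -> float:
        return 0.5 * (self.start_t + self.end_t)


@dataclass
class DwellTimecourse:
    """AOI dwell (ms) in eight 1 s bins over [trigger-4 s, trigger+4 s)."""

    change_id: str
    bins_ms: np.ndarray  # shape (8,), bin k covers [trigger-4+k, trigger-3+k)

    @property
    def dwell_pre_ms(self) -> float:
        return float(self.bins_ms[:4].sum())

    @property
    def dwell_post_ms(self) -> float:
        return float(self.bins_ms[4:].sum())

    def dwell_window_ms(self, pre_s: float, post_s: float) -> tuple[float, float]:
        """Dwell totals restricted to [trigger-pre_s, trigger) and
        [trigger, trigger+post_s); windows must be whole seconds <= 4."""
        pre_k, post_k = int(round(pre_s)), int(round(post_s))
        if not (0 < pre_k <= 4 and 0 < post_k <= 4):
            raise ValueError("dwell windows must be whole seconds in (0, 4]")
        return float(self.bins_ms[4 - pre_k : 4].sum()), float(self.bins_ms[4 : 4 + post_k].sum())


def angular_separation(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two unit 3-vectors, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angular_separation requires non-zero vectors")
    cosang = float(np.dot(a, b)) / (na * nb)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _max_pairwise_deg(dirs: np.ndarray) -> float:
    """Exact maximum pairwise angular separation (degrees) of unit rows."""
    if dirs.shape[0] < 2:
        return 0.0
    g = dirs @ dirs.T
    return math.degrees(math.acos(max(-1.0, min(1.0, float(g.min())))))


def _chord_deg(chord: float) -> float:
    return math.degrees(2.0 * math.asin(min(1.0, 0.5 * chord)))


def _emit_split(
    t: np.ndarray,
    dirs: np.ndarray,
    i: int,
    j: int,
    min_dur_s: float,
    max_dur_s: float,
    split_long: bool,
    out: list[Fixation],
) -> None:
    """Emit window samples i..j (inclusive) as one or more fixations."""
    dur = float(t[j] - t[i])
    if split_long and dur > max_dur_s:
        k = max(1, math.ceil((dur - 1e-12) / max_dur_s))
    else:
        k = 1
    edges = t[i] + dur * np.arange(k + 1) / k
    idx = np.arange(i, j + 1)
    for m in range(k):
        lo, hi = edges[m], edges[m + 1]
        if m == k - 1:
            sel = idx[(t[idx] >= lo - 1e-12)]
        else:
            sel = idx[(t[idx] >= lo - 1e-12) & (t[idx] < hi - 1e-12)]
        if sel.size < 2:
            continue
        span = float(t[sel[-1]] - t[sel[0]])
        if span < min_dur_s:
            continue
        sub = dirs[sel]
        centroid = sub.mean(axis=0)
        centroid /= np.linalg.norm(centroid)
        out.append(
            Fixation(
                start_t=float(t[sel[0]]),
                end_t=float(t[sel[-1]]),
                centroid_dir=centroid,
                dispersion_deg=_max_pairwise_deg(sub),
            )
        )


def _idt_segment(
    t: np.ndarray,
    dirs: np.ndarray,
    dispersion_deg: float,
    min_dur_s: float,
    max_dur_s: float,
    split_long: bool,
    out: list[Fixation],
) -> None:
    """Greedy leftmost-maximal I-DT on one gap-free run of valid samples.

    The pairwise-dispersion test is accelerated with a per-axis bounding box
    on the unit directions: the box diagonal upper-bounds, and the largest
    per-axis extent lower-bounds, the maximum pairwise chord. Only when the
    threshold falls between the two bounds is the exact pairwise maximum
    computed, so long stable windows grow in O(1) per sample.
    """
    n = t.size
    thr = dispersion_deg
    i = 0
    while i < n - 1:
        mins = dirs[i].copy()
        maxs = dirs[i].copy()
        j = i
        while j + 1 < n:
            cand = dirs[j + 1]
            nmins = np.minimum(mins, cand)
            nmaxs = np.maximum(maxs, cand)
            ext = nmaxs - nmins
            ub = _chord_deg(float(np.linalg.norm(ext)))
            if ub <= thr:
                mins, maxs = nmins, nmaxs
                j += 1
                continue
            lb = _chord_deg(float(ext.max()))
            if lb > thr:
                break
            if _max_pairwise_deg(dirs[i : j + 2]) <= thr:
                mins, maxs = nmins, nmaxs
                j += 1
                continue
            break
        if float(t[j] - t[i]) >= min_dur_s:
            _emit_split(t, dirs, i, j, min_dur_s, max_dur_s, split_long, out)
            i = j + 1
        else:
            i += 1


def detect_fixations(
    gaze: GazeStream,
    dispersion_deg: float = DEFAULT_DISPERSION_DEG,
    min_dur_s: float = DEFAULT_MIN_DUR_S,
    max_dur_s: float = DEFAULT_MAX_DUR_S,
    max_sample_gap_s: float = DEFAULT_MAX_SAMPLE_GAP_S,
    split_long: bool = True,
) -> list[Fixation]:
    """Dispersion-threshold fixation detection on a gaze stream.

    Parameters
    ----------
    dispersion_deg : maximum pairwise angular separation permitted within a
        fixation window; the tracker guideline band is 0.7-1.3 degrees and
        the default sits at its midpoint.
    min_dur_s, max_dur_s : fixation duration band (100-500 ms by default).
    max_sample_gap_s : inter-sample gaps longer than this break the window
        (prevents bridging blinks).
    split_long : split windows exceeding ``max_dur_s`` into consecutive
        fixations instead of discarding them.

    Returns time-ordered, non-overlapping fixations. Fewer than two samples
    yield an empty list; non-monotone timestamps raise ValidationError.
    """
    t_all = np.asarray(gaze.t, dtype=float)
    if t_all.size >= 2 and np.any(np.diff(t_all) <= 0):
        raise ValidationError("detect_fixations: gaze timestamps must be strictly increasing")
    if t_all.size < 2:
        return []

    out: list[Fixation] = []
    valid_idx = np.nonzero(gaze.valid)[0]
    if valid_idx.size < 2:
        return []
    # split valid samples into runs broken by invalid samples or long gaps
    breaks = np.nonzero(
        (np.diff(valid_idx) > 1)
        | (np.diff(t_all[valid_idx]) > max_sample_gap_s)
    )[0]
    start = 0
    for b in np.append(breaks, valid_idx.size - 1):
        run = valid_idx[start : b + 1]
        start = b + 1
        if run.size >= 2:
            _idt_segment(
                t_all[run],
                np.asarray(gaze.gaze_dir, dtype=float)[run],
                dispersion_deg,
                min_dur_s,
                max_dur_s,
                split_long,
                out,
            )
    return out


def _interp_head(gaze: GazeStream, t: float) -> np.ndarray:
    out = np.empty(3)
    for k in range(3):
        out[k] = np.interp(t, gaze.t, gaze.head_pos[:, k])
    return out


def aoi_dwell(
    fixations: list[Fixation],
    gaze: GazeStream,
    aoi: AOI,
    window: tuple[float, float],
) -> list[tuple[float, float]]:
    """Fixation sub-intervals landing on ``aoi``, clipped to ``window``.

    A fixation lands when its centroid direction is within the AOI's angular
    radius of the head-to-centre direction at the fixation midpoint. Returns
    half-open (start, end) interval pairs; saccade time never contributes.
    """
    a, b = window
    if not aoi.covers(a, b):
        raise CoverageError(
            f"AOI {aoi.aoi_id} track [{aoi.track_t[0]:.6g}, {aoi.track_t[-1]:.6g}] "
            f"does not cover window [{a:.6g}, {b:.6g}]"
        )
    hits: list[tuple[float, float]] = []
    for fx in fixations:
        if fx.end_t <= a or fx.start_t >= b:
            continue
        mid = fx.midpoint_t
        head = _interp_head(gaze, mid)
        vec = aoi.center_at(mid) - head
        dist = float(np.linalg.norm(vec))
        if dist <= aoi.radius:
            # head inside the AOI sphere: everything counts as on-AOI
            ang_radius = 180.0
        else:
            ang_radius = math.degrees(math.atan(aoi.radius / dist))
        if angular_separation(fx.centroid_dir, vec) <= ang_radius:
            lo, hi = max(fx.start_t, a), min(fx.end_t, b)
            if hi > lo:
                hits.append((lo, hi))
    return hits


def event_timecourse(
    fixations: list[Fixation],
    gaze: GazeStream,
    event: ChangeEvent,
    aoi: AOI,
    pre_s: float = 4.0,
    post_s: float = 4.0,
) -> DwellTimecourse:
    """Eight-bin AOI dwell time-course around a change trigger.

    Dwell from :func:`aoi_dwell` over ``[trigger-4, trigger+4)`` is
    apportioned to eight half-open 1 s bins (milliseconds per bin); bin
    sums equal the total clipped dwell exactly.
    """
    t0 = event.trigger_t
    intervals = aoi_dwell(fixations, gaze, aoi, (t0 - pre_s, t0 + post_s))
    edges = t0 + np.arange(-4, 5, dtype=float)
    bins = np.zeros(8)
    for lo, hi in intervals:
        for k in range(8):
            overlap = min(hi, edges[k + 1]) - max(lo, edges[k])
            if overlap > 0:
                bins[k] += overlap * 1000.0
    return DwellTimecourse(change_id=event.change_id, bins_ms=bins)
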