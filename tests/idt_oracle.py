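"""Exhaustive-window reference implementation of dispersion-threshold
fixation detection, used only as a test oracle.

Works from the full pairwise angular-separation matrix, growing each
candidate window sample by sample with a brute-force running maximum, so it
shares no code path with the production detector (which uses bounding-box
pruning and never materialises the matrix).
"""

from __future__ import annotations

import math

import numpy as np


def pairwise_deg(dirs: np.ndarray) -> np.ndarray:
    g = np.clip(dirs @ dirs.T, -1.0, 1.0)
    return np.degrees(np.arccos(g))


def split_window(t: np.ndarray, i: int, j: int, min_dur: float, max_dur: float, split: bool):
    """Equal-span splitting of a maximal window, mirroring the documented
    rule: k = ceil(duration/max_dur) chunks of equal time span; chunks
    shorter than min_dur (or with < 2 samples) are dropped."""
    dur = t[j] - t[i]
    k = max(1, math.ceil((dur - 1e-12) / max_dur)) if (split and dur > max_dur) else 1
    edges = [t[i] + dur * m / k for m in range(k + 1)]
    out = []
    for m in range(k):
        lo, hi = edges[m], edges[m + 1]
        sel = [
            q
            for q in range(i, j + 1)
            if t[q] >= lo - 1e-12 and (m == k - 1 or t[q] < hi - 1e-12)
        ]
        if len(sel) >= 2 and t[sel[-1]] - t[sel[0]] >= min_dur:
            out.append((sel[0], sel[-1]))
    return out


def oracle_runs(t: np.ndarray, valid: np.ndarray, max_gap: float):
    """Valid-sample runs broken at invalid samples and long gaps."""
    idx = np.nonzero(valid)[0]
    runs, cur = [], []
    for k in idx:
        if cur and (k != cur[-1] + 1 or t[k] - t[cur[-1]] > max_gap):
            runs.append(cur)
            cur = []
        cur.append(k)
    if cur:
        runs.append(cur)
    return [r for r in runs if len(r) >= 2]


def oracle_idt(
    t: np.ndarray,
    dirs: np.ndarray,
    valid: np.ndarray,
    thr: float,
    min_dur: float = 0.100,
    max_dur: float = 0.500,
    max_gap: float = 0.050,
    split: bool = True,
) -> list[tuple[int, int]]:
    """Greedy leftmost-maximal windows, checked against every window end."""
    out: list[tuple[int, int]] = []
    for run in oracle_runs(t, valid, max_gap):
        sub = np.asarray(run)
        A = pairwise_deg(dirs[sub])
        tt = t[sub]
        n = len(run)
        i = 0
        while i < n - 1:
            j, cur = i, 0.0
            while j + 1 < n:
                cand = max(cur, float(A[j + 1, i : j + 2].max()))
                if cand <= thr:
                    j += 1
                    cur = cand
                else:
                    break
            if tt[j] - tt[i] >= min_dur:
                out.extend(
                    (int(sub[a]), int(sub[b]))
                    for a, b in split_window(tt, i, j, min_dur, max_dur, split)
                )
                i = j + 1
            else:
                i += 1
    return out
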