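"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most literal method available —
double loops, exhaustive enumeration, optimal assignment — staying
independent of the library code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def brute_force_msd(frames, xy, lag: int) -> tuple[float, int]:
    """MSD at a frame lag by an explicit double loop over all pairs."""
    frames = list(frames)
    total, count = 0.0, 0
    for i in range(len(frames)):
        for j in range(len(frames)):
            if frames[j] - frames[i] == lag:
                dx = xy[j][0] - xy[i][0]
                dy = xy[j][1] - xy[i][1]
                total += dx * dx + dy * dy
                count += 1
    return (total / count if count else float("nan")), count


def optimal_assignment_linking(locs, max_disp_um: float, max_gap: int):
    """Frame-by-frame minimal-total-displacement linking.

    ``locs`` is a list of (frame, x, y). At each frame the candidate
    (open track, localization) pairs within the displacement/gap caps are
    matched by the Hungarian algorithm minimizing summed distance.
    Returns a list of tracks, each a list of indices into ``locs``.
    """
    order = sorted(range(len(locs)), key=lambda i: locs[i][0])
    tracks: list[list[int]] = []
    last: list[tuple[int, float, float]] = []  # (frame, x, y) per track
    i = 0
    while i < len(order):
        f = locs[order[i]][0]
        batch = []
        while i < len(order) and locs[order[i]][0] == f:
            batch.append(order[i])
            i += 1
        open_idx = [
            k for k, (lf, _, _) in enumerate(last) if 0 < f - lf <= max_gap + 1
        ]
        if open_idx and batch:
            cost = np.full((len(open_idx), len(batch)), 1e9)
            for a, k in enumerate(open_idx):
                _, lx, ly = last[k]
                for b, j in enumerate(batch):
                    d = np.hypot(locs[j][1] - lx, locs[j][2] - ly)
                    if d <= max_disp_um:
                        cost[a, b] = d
            rows, cols = linear_sum_assignment(cost)
            assigned = set()
            for a, b in zip(rows, cols):
                if cost[a, b] < 1e9:
                    k = open_idx[a]
                    j = batch[b]
                    tracks[k].append(j)
                    last[k] = (f, locs[j][1], locs[j][2])
                    assigned.add(j)
        else:
            assigned = set()
        for j in batch:
            if j not in assigned:
                tracks.append([j])
                last.append((f, locs[j][1], locs[j][2]))
    return tracks


def runs_by_enumeration(labels):
    """Maximal equal-label runs via explicit scanning."""
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        out.append((labels[i], i, j))
        i = j + 1
    return out


def transitions_by_enumeration(labels, frames, dt):
    """Inter-synaptic transitions from first principles on a label list."""
    runs = [r for r in runs_by_enumeration(labels) if r[0] != -1]
    events = []
    for (a, _, ae), (b, bs, _) in zip(runs, runs[1:]):
        if a != b:
            events.append((a, b, frames[ae], frames[bs], (frames[bs] - frames[ae]) * dt))
    return events


def disk_membership_raster(point, center, radius: float, grid: float = 1e-4) -> bool:
    """Membership in a disk decided on a fine raster (no analytic compare)."""
    dx = round((point[0] - center[0]) / grid) * grid
    dy = round((point[1] - center[1]) / grid) * grid
    return dx * dx + dy * dy <= radius * radius + grid
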