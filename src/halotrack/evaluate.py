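"""Comparing recovered tracks against simulated ground truth."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Track

__all__ = ["MatchResult", "match_tracks"]


@dataclass
class MatchResult:
    """Assignment of recovered tracks to ground-truth cells.

    ``assignment`` maps each recovered track's qualified id to the matched
    truth track's qualified id; ``rmse_um`` is the root-mean-square
    distance between every recovered point and its matched truth position
    at the same frame.  ``rmse_nearest_um`` instead measures each point
    against the nearest ground-truth cell at that frame - pure localization
    accuracy, insensitive to the rare identity exchange when two crossing
    cells tumble while their spots overlap (identity errors show up in the
    track counts, not here).
    """

    assignment: dict[str, str]
    rmse_um: float
    rmse_nearest_um: float
    n_points: int

    def n_matched_to(self, predicate) -> int:
        return sum(1 for v in self.assignment.values() if predicate(v))


def match_tracks(recovered: list[Track], truth: list[Track]) -> MatchResult:
    """Match each recovered track to the nearest ground-truth cell.

    For every (recovered, truth) pair the mean distance over common frames
    is computed; each recovered track is assigned the truth track
    minimizing it.  Several recovered fragments may map to one truth cell;
    the per-point RMSE is over all assigned points.
    """
    truth_by_frame = []
    for tt in truth:
        idx = {int(f): i for i, f in enumerate(tt.frames)}
        truth_by_frame.append((tt, idx))
    assignment: dict[str, str] = {}
    sq_sum = 0.0
    sq_sum_nearest = 0.0
    n_pts = 0
    for rt in recovered:
        best = None
        best_mean = math.inf
        for tt, idx in truth_by_frame:
            dists = []
            for i, f in enumerate(rt.frames):
                j = idx.get(int(f))
                if j is None:
                    continue
                dists.append(
                    (rt.x[i] - tt.x[j]) ** 2 + (rt.y[i] - tt.y[j]) ** 2
                )
            if dists:
                m = float(np.mean(dists))
                if m < best_mean:
                    best_mean = m
                    best = (tt, idx)
        if best is None:
            continue
        tt, idx = best
        assignment[rt.qualified_id] = tt.qualified_id
        for i, f in enumerate(rt.frames):
            j = idx.get(int(f))
            if j is None:
                continue
            sq_sum += (rt.x[i] - tt.x[j]) ** 2 + (rt.y[i] - tt.y[j]) ** 2
            nearest = math.inf
            for ot, oidx in truth_by_frame:
                oj = oidx.get(int(f))
                if oj is None:
                    continue
                d2 = (rt.x[i] - ot.x[oj]) ** 2 + (rt.y[i] - ot.y[oj]) ** 2
                if d2 < nearest:
                    nearest = d2
            sq_sum_nearest += nearest
            n_pts += 1
    rmse = math.sqrt(sq_sum / n_pts) if n_pts else float("nan")
    rmse_nearest = math.sqrt(sq_sum_nearest / n_pts) if n_pts else float("nan")
    return MatchResult(
        assignment=assignment, rmse_um=rmse, rmse_nearest_um=rmse_nearest, n_points=n_pts
    )
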