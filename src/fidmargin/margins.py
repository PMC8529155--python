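"""Tracking-margin determination by optimal fiducial-subset selection.

Given the tumor (GTV) motion trace u_T and the traces of the N_F implanted
fiducials, every non-empty marker subset S is scored by the RMS discrepancy

    f(S) = sqrt( (1 / (3 P)) * sum_phases sum_axes (u_T - u_S)^2 ),

where u_S is the per-phase mean trace of the subset's markers and P the
phase count.  The optimum S* = argmin f(S) is found by exhaustive
enumeration, and the per-axis ITV_tracking margin is the worst-phase
absolute discrepancy between u_T and u_S* on each of the R-L, A-P and I-S
axes — the expansion needed to cover the residual target-to-marker motion
mismatch when tracking the subset instead of the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .phantom import MotionTrace

__all__ = [
    "SubsetScore",
    "MarginResult",
    "subset_mean_trace",
    "f_score",
    "select_optimal_subset",
    "MAX_ENUMERATION_MARKERS",
]

MAX_ENUMERATION_MARKERS = 12  # 2^12 - 1 subsets; guards combinatorial misuse


@dataclass
class SubsetScore:
    subset: tuple
    f_value: float
    per_axis_max_abs_diff: np.ndarray  # (3,) mm


@dataclass
class MarginResult:
    gtv_id: str
    optimal_subset: tuple
    itv_tracking_margin_mm: np.ndarray       # (R-L, A-P, I-S) mm
    f_optimal: float
    gtv_to_marker_distance_mm: dict = field(default_factory=dict)
    all_scores: list = field(default_factory=list)


def _trace_map(trajectories: Sequence[MotionTrace]) -> dict:
    out = {}
    for tr in trajectories:
        out[tr.object_id] = tr
    return out


def subset_mean_trace(trajectories: Sequence[MotionTrace], subset) -> MotionTrace:
    """Per-phase arithmetic mean of the member markers' displacement traces."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    traces = _trace_map(trajectories)
    missing = [i for i in subset if i not in traces]
    if missing:
        raise KeyError(f"unknown marker id(s): {missing}")
    if len({traces[i].displacement_mm.shape[0] for i in subset}) > 1:
        raise ValueError("member traces have differing phase counts")
    stack = np.stack([traces[i].displacement_mm for i in subset])
    return MotionTrace(
        object_id="mean(" + ",".join(str(i) for i in subset) + ")",
        displacement_mm=stack.mean(axis=0),
    )


def f_score(u_t: MotionTrace, u_s: MotionTrace) -> SubsetScore:
    """RMS discrepancy between a target trace and a subset-mean trace.

    Pools all phases and all three axes:
    f = sqrt(mean over 3P terms of (u_T - u_S)^2).  Also reports, per
    axis, the maximum absolute per-phase difference (the quantity the
    tracking margin must cover).
    """
    if u_t.n_phases != u_s.n_phases:
        raise ValueError(
            f"phase counts differ: {u_t.n_phases} vs {u_s.n_phases}")
    diff = u_t.displacement_mm - u_s.displacement_mm
    f = float(np.sqrt(np.mean(diff ** 2)))
    return SubsetScore(
        subset=(),
        f_value=f,
        per_axis_max_abs_diff=np.max(np.abs(diff), axis=0),
    )


def select_optimal_subset(
    u_t: MotionTrace,
    trajectories: Sequence[MotionTrace],
    candidate_ids: Optional[Sequence] = None,
    marker_positions_mm: Optional[Mapping] = None,
    gtv_position_mm=None,
) -> MarginResult:
    """Exhaustively enumerate marker subsets and pick the best-synchronized.

    Evaluates all 2^N_F - 1 non-empty subsets of ``candidate_ids``
    (default: every trajectory id).  S* minimizes f; exact ties are broken
    by fewer markers, then smaller mean GTV-to-marker distance (when
    positions are supplied), then lexicographic id order.  The ITV_tracking
    margin of S* is its per-axis worst-phase discrepancy.
    """
    traces = _trace_map(trajectories)
    ids = tuple(candidate_ids) if candidate_ids is not None else tuple(traces)
    if not ids:
        raise ValueError("candidate_ids must be non-empty")
    if len(ids) > MAX_ENUMERATION_MARKERS:
        raise ValueError(
            f"{len(ids)} candidate markers exceed the exhaustive-enumeration "
            f"cap of {MAX_ENUMERATION_MARKERS}")

    distances = {}
    if marker_positions_mm is not None and gtv_position_mm is not None:
        g = np.asarray(gtv_position_mm, float)
        distances = {
            i: float(np.linalg.norm(np.asarray(p, float) - g))
            for i, p in marker_positions_mm.items()
        }

    def mean_distance(subset) -> float:
        if not distances:
            return 0.0
        return float(np.mean([distances.get(i, 0.0) for i in subset]))

    scores: list[SubsetScore] = []
    for r in range(1, len(ids) + 1):
        for subset in combinations(ids, r):
            sc = f_score(u_t, subset_mean_trace(trajectories, subset))
            sc.subset = subset
            scores.append(sc)

    best = min(
        scores,
        key=lambda s: (s.f_value, len(s.subset), mean_distance(s.subset),
                       tuple(str(i) for i in s.subset)),
    )
    return MarginResult(
        gtv_id=u_t.object_id,
        optimal_subset=best.subset,
        itv_tracking_margin_mm=best.per_axis_max_abs_diff.copy(),
        f_optimal=best.f_value,
        gtv_to_marker_distance_mm={i: distances[i] for i in best.subset
                                   if i in distances},
        all_scores=scores,
    )
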