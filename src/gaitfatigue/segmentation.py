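"""Gait-cycle identification from total plantar force.

Heel strike and toe off are detected by thresholding the summed regional
plantar force at 10 N, the standard event threshold for force-based gait
segmentation.  The thresholded signal is the sum of all seven regional
channels — the closest available proxy for vertical ground reaction force
with discrete sensors.  Debouncing (minimum stance/swing run lengths)
suppresses chatter at the threshold crossing.

Within each cycle the flat-foot window is taken as 15–25% of the cycle:
foot-flat and heel-off fall near 10% and 30% of the cycle, so this span is
the quiescent mid-stance interval used as the rotation-angle reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ContractError, SensorRecording

__all__ = [
    "GaitEvent",
    "GaitCycle",
    "total_force",
    "detect_gait_cycles",
    "flat_foot_window",
    "segment_recording",
]

CYCLE_THRESHOLD_N = 10.0
MIN_STANCE_S = 0.2
MIN_SWING_S = 0.1


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # "heel_strike" | "toe_off"
    sample_index: int
    time_s: float


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle: half-open span [hs_index, next_hs_index).

    ``flat_start``/``flat_end`` delimit the half-open flat-foot window at
    15–25% of the cycle.
    """

    hs_index: int
    to_index: int
    next_hs_index: int
    flat_start: int
    flat_end: int

    def __post_init__(self) -> None:
        if not (self.hs_index < self.to_index < self.next_hs_index):
            raise ContractError(
                f"cycle indices must satisfy hs < to < next_hs, got "
                f"({self.hs_index}, {self.to_index}, {self.next_hs_index})"
            )

    @property
    def length(self) -> int:
        return self.next_hs_index - self.hs_index


def total_force(rec: SensorRecording) -> np.ndarray:
    """Elementwise sum of the seven regional force channels, in N."""
    return rec.force.sum(axis=1)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def flat_foot_window(cycle_start: int, cycle_end: int) -> tuple[int, int]:
    """Flat-foot span [start, end) at 15–25% of the cycle [cycle_start, cycle_end).

    Indices are rounded half-away-from-zero.  Cycles shorter than 8 samples
    cannot host a non-empty window and are rejected as degenerate.
    """
    if cycle_end <= cycle_start:
        raise ContractError("cycle_end must exceed cycle_start")
    length = cycle_end - cycle_start
    if length < 8:
        raise ContractError(f"degenerate cycle of {length} samples (< 8)")
    flat_start = cycle_start + _round_half_away(0.15 * length)
    flat_end = cycle_start + _round_half_away(0.25 * length)
    if flat_end < flat_start + 1:
        flat_end = flat_start + 1
    return flat_start, flat_end


def _runs(above: np.ndarray) -> list[tuple[bool, int, int]]:
    """Maximal constant runs of a boolean array as (value, start, end)."""
    n = above.shape[0]
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [n]))
    return [(bool(above[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _merge_short_runs(
    above: np.ndarray, value: bool, min_len: int
) -> np.ndarray:
    """Flip interior runs of *value* shorter than *min_len* (debounce)."""
    out = above.copy()
    for val, s, e in _runs(above):
        if val == value and e - s < min_len and s > 0 and e < above.shape[0]:
            out[s:e] = not value
    return out


def detect_gait_cycles(
    total: np.ndarray,
    threshold_N: float = CYCLE_THRESHOLD_N,
    min_stance_s: float = MIN_STANCE_S,
    min_swing_s: float = MIN_SWING_S,
    fs: float = 110.0,
) -> list[GaitCycle]:
    """Detect complete gait cycles from a total plantar force series.

    Heel strike is the first sample at or above *threshold_N* after a
    below-threshold run of at least *min_swing_s*; toe off is the first
    sample below threshold after an above-threshold run of at least
    *min_stance_s*.  Shorter runs are treated as chatter and merged into
    the surrounding phase.  Incomplete leading/trailing cycles are
    discarded; a series that never crosses threshold yields an empty list.
    """
    total = np.asarray(total, dtype=float)
    if total.shape[0] < 2:
        raise ContractError("force series must have length >= 2")
    if not threshold_N > 0:
        raise ContractError("threshold must be positive")
    above = total >= threshold_N
    if not above.any() or above.all():
        return []
    min_swing = max(1, int(np.ceil(min_swing_s * fs)))
    min_stance = max(1, int(np.ceil(min_stance_s * fs)))
    # debounce: swallow sub-swing gaps inside stance, then sub-stance blips
    above = _merge_short_runs(above, False, min_swing)
    above = _merge_short_runs(above, True, min_stance)

    hs_indices: list[int] = []
    to_indices: list[int] = []
    runs = _runs(above)
    for i, (val, s, e) in enumerate(runs):
        if val and i > 0 and (s - runs[i - 1][1]) >= min_swing:
            # stance preceded by an in-record swing of sufficient length
            hs_indices.append(s)
            if e < total.shape[0]:
                to_indices.append(e)

    # after debouncing, runs alternate, so toe-off k pairs with heel strike k
    cycles: list[GaitCycle] = []
    for k in range(len(hs_indices) - 1):
        hs, to, next_hs = hs_indices[k], to_indices[k], hs_indices[k + 1]
        fl_s, fl_e = flat_foot_window(hs, next_hs)
        cycles.append(GaitCycle(hs, to, next_hs, fl_s, fl_e))
    return cycles


def segment_recording(
    rec: SensorRecording,
    threshold_N: float = CYCLE_THRESHOLD_N,
    min_stance_s: float = MIN_STANCE_S,
    min_swing_s: float = MIN_SWING_S,
) -> list[GaitCycle]:
    """Convenience wrapper: detect cycles on the recording's total force."""
    return detect_gait_cycles(
        total_force(rec),
        threshold_N=threshold_N,
        min_stance_s=min_stance_s,
        min_swing_s=min_swing_s,
        fs=rec.fs,
    )
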