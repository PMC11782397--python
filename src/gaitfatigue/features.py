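"""Per-cycle biomechanical features and windowed dataset construction.

Forty-nine features are computed per gait cycle:

* 28 force features — contact time (CT, s), peak force (PF, N), impulse
  (Imp, N·s) and the coefficient of variation of force (FCV, unitless) at
  each of the seven plantar regions;
* 12 resultant-signal features — maximum, RMS and CV of the resultant
  acceleration (m/s^2), resultant jerk (m/s^3), resultant angular velocity
  (deg/s) and resultant angular acceleration (deg/s^2);
* 9 angle features — maximum, range and CV of the rotation angle in the
  sagittal, coronal and transverse planes (deg).

Rotation angles are expressed relative to the quiescent flat-foot phase of
each cycle: the mean angle over the 15–25% flat-foot window is subtracted
from the whole cycle, which removes constant offsets exactly and slow
integration drift up to the amount accumulated within one cycle.

Cycles are aggregated into sliding 10-s windows (8-s overlap by default) by
averaging the per-cycle feature vectors of all cycles whose heel strike
falls inside the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ConfigError, ContractError, FORCE_REGIONS, SensorRecording
from .segmentation import (
    CYCLE_THRESHOLD_N,
    MIN_STANCE_S,
    MIN_SWING_S,
    GaitCycle,
    segment_recording,
)

__all__ = [
    "FEATURE_NAMES",
    "FORCE_FEATURES",
    "IMU_FEATURES",
    "WindowSample",
    "ExtractionParams",
    "coefficient_of_variation",
    "jerk_series",
    "resultant_magnitude",
    "correct_angle_drift",
    "region_contact_features",
    "extract_cycle_features",
    "make_windows",
    "build_dataset",
]

logger = logging.getLogger(__name__)

_RES_SIGNALS = ("acc_Res", "j_Res", "w_Res", "alpha_Res")
_RES_STATS = ("Max", "RMS", "CV")
_PLANES = ("Sag", "Cor", "Tra")
_ANGLE_STATS = ("Max", "Ran", "CV")

#: The 28 force-based feature names, in canonical (table) order.
FORCE_FEATURES: tuple[str, ...] = tuple(
    f"{kind}_{r}" for kind in ("CT", "PF", "Imp", "FCV") for r in FORCE_REGIONS
)

#: The 21 IMU-based feature names, in canonical (table) order.
IMU_FEATURES: tuple[str, ...] = tuple(
    f"{sig}_{stat}" for sig in _RES_SIGNALS for stat in _RES_STATS
) + tuple(f"theta_{p}_{stat}" for p in _PLANES for stat in _ANGLE_STATS)

#: All 49 per-cycle feature names.
FEATURE_NAMES: tuple[str, ...] = FORCE_FEATURES + IMU_FEATURES


@dataclass
class WindowSample:
    """One 10-s window: cycle-averaged features plus its state label."""

    participant_id: str
    state_label: str  # "non_fatigue" | "fatigue"
    window_start_s: float
    n_cycles: int
    features: dict[str, float]


@dataclass
class ExtractionParams:
    """Tunable parameters of segmentation, feature extraction and windowing."""

    cycle_threshold_N: float = CYCLE_THRESHOLD_N
    region_threshold_N: float = 1.0
    min_stance_s: float = MIN_STANCE_S
    min_swing_s: float = MIN_SWING_S
    window_s: float = 10.0
    overlap_s: float = 8.0
    count_mode: str = "formula"  # "formula" | "strict"
    min_cycles_per_window: int = 3
    segment_duration_s: float | None = None  # None: use the recording length
    aggregation: str = "mean"
    swing_only: bool = False

    def __post_init__(self) -> None:
        if self.window_s <= self.overlap_s or self.overlap_s < 0:
            raise ConfigError("require window_s > overlap_s >= 0")
        if self.count_mode not in ("formula", "strict"):
            raise ConfigError(f"unknown count_mode {self.count_mode!r}")
        if self.aggregation != "mean":
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.min_cycles_per_window < 1:
            raise ConfigError("min_cycles_per_window must be >= 1")


# ---------------------------------------------------------------------------
# elementary statistics

def coefficient_of_variation(x: np.ndarray, eps: float = 1e-9) -> float:
    """Sample standard deviation divided by the absolute mean.

    Near-zero means (|mean| < *eps*) would blow the ratio up; such cases
    return the sentinel 0.0 with a logged flag so that aggregation and model
    training are not poisoned by infinities.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ContractError("coefficient_of_variation requires length >= 2")
    m = abs(float(np.mean(x)))
    if m < eps:
        logger.debug("CV sentinel: |mean| < %.1e, returning 0", eps)
        return 0.0
    return float(np.std(x, ddof=1)) / m


def jerk_series(acc: np.ndarray, fs: float) -> np.ndarray:
    """First time-derivative of an acceleration series (m/s^3).

    Central finite differences at interior points, one-sided at the ends
    (exact for linear signals).
    """
    acc = np.asarray(acc, dtype=float)
    if acc.shape[0] < 3:
        raise ContractError("jerk_series requires length >= 3")
    return np.gradient(acc, axis=0) * fs


def resultant_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a triaxial signal."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ContractError("resultant_magnitude requires equal-length axes")
    return np.sqrt(x * x + y * y + z * z)


def correct_angle_drift(theta: np.ndarray, cycle: GaitCycle) -> np.ndarray:
    """Re-reference one cycle of a rotation angle to its flat-foot phase.

    Returns ``theta[i] - mean(theta over the flat window)`` for all samples
    of the cycle, so the corrected series has exactly zero mean over the
    flat window.  Idempotent: correcting a corrected cycle changes nothing.
    """
    theta = np.asarray(theta, dtype=float)
    if cycle.next_hs_index > theta.shape[0]:
        raise ContractError("cycle indices exceed series length")
    if cycle.flat_end <= cycle.flat_start:
        raise ContractError("empty flat-foot window")
    ref = float(np.mean(theta[cycle.flat_start : cycle.flat_end]))
    return theta[cycle.hs_index : cycle.next_hs_index] - ref


def region_contact_features(
    force_r: np.ndarray,
    cycle: GaitCycle,
    region_threshold_N: float = 1.0,
    fs: float = 110.0,
) -> tuple[float, float, float, float]:
    """(CT, PF, Imp, FCV) for one regional force channel over one cycle.

    Contact time counts samples at or above the contact threshold; impulse
    is the discrete integral of the above-threshold force, each contact
    sample contributing its full 1/fs dwell (so a constant 50 N contact of
    0.5 s carries exactly 25 N·s, and the result equals the trapezoidal
    rule whenever the force vanishes at the contact edges); FCV is the CV
    of the above-threshold force.  A region that never reaches threshold
    contributes CT = 0, Imp = 0, FCV = 0 and PF = its maximum over the
    cycle.  The contact threshold (default 1 N) is deliberately far below
    the 10 N cycle threshold: the small arch sensors carry only ~1 N·s of
    impulse and would be zeroed out at 10 N.
    """
    if not region_threshold_N > 0:
        raise ContractError("region threshold must be positive")
    f = np.asarray(force_r, dtype=float)[cycle.hs_index : cycle.next_hs_index]
    mask = f >= region_threshold_N
    pf = float(f.max())
    if not mask.any():
        return 0.0, pf, 0.0, 0.0
    ct = float(mask.sum()) / fs
    imp = float(f[mask].sum()) / fs
    fcv = coefficient_of_variation(f[mask]) if mask.sum() >= 2 else 0.0
    return ct, pf, imp, fcv


def _stats_triplet(x: np.ndarray) -> tuple[float, float, float]:
    """(Max, RMS, CV) of a series."""
    return (
        float(np.max(x)),
        float(np.sqrt(np.mean(x * x))),
        coefficient_of_variation(x),
    )


def extract_cycle_features(
    rec: SensorRecording,
    cycle: GaitCycle,
    params: ExtractionParams | None = None,
) -> dict[str, float]:
    """All 49 features of one gait cycle, keyed by canonical feature name.

    Resultant-signal statistics are taken over the full cycle by default;
    with ``params.swing_only`` they are restricted to the swing phase
    (toe off to next heel strike).  Angle statistics are always computed on
    the drift-corrected full cycle.
    """
    params = params or ExtractionParams()
    fs = rec.fs
    sl = slice(cycle.hs_index, cycle.next_hs_index)
    out: dict[str, float] = {}

    for j, region in enumerate(FORCE_REGIONS):
        ct, pf, imp, fcv = region_contact_features(
            rec.force[:, j], cycle, params.region_threshold_N, fs
        )
        out[f"CT_{region}"] = ct
        out[f"PF_{region}"] = pf
        out[f"Imp_{region}"] = imp
        out[f"FCV_{region}"] = fcv

    acc = rec.acc[sl]
    gyr = rec.gyr[sl]
    acc_res = resultant_magnitude(acc[:, 0], acc[:, 1], acc[:, 2])
    jrk = jerk_series(acc, fs)
    j_res = resultant_magnitude(jrk[:, 0], jrk[:, 1], jrk[:, 2])
    w_res = resultant_magnitude(gyr[:, 0], gyr[:, 1], gyr[:, 2])
    alp = jerk_series(gyr, fs)  # same central-difference derivative
    alpha_res = resultant_magnitude(alp[:, 0], alp[:, 1], alp[:, 2])

    if params.swing_only:
        sw = slice(cycle.to_index - cycle.hs_index, None)
        acc_res, j_res = acc_res[sw], j_res[sw]
        w_res, alpha_res = w_res[sw], alpha_res[sw]

    for name, series in zip(_RES_SIGNALS, (acc_res, j_res, w_res, alpha_res)):
        mx, rms, cv = _stats_triplet(series)
        out[f"{name}_Max"] = mx
        out[f"{name}_RMS"] = rms
        out[f"{name}_CV"] = cv

    for j, plane in enumerate(_PLANES):
        corrected = correct_angle_drift(rec.ang[:, j], cycle)
        out[f"theta_{plane}_Max"] = float(corrected.max())
        out[f"theta_{plane}_Ran"] = float(corrected.max() - corrected.min())
        out[f"theta_{plane}_CV"] = coefficient_of_variation(corrected)
    return out


# ---------------------------------------------------------------------------
# windowing

def make_windows(
    segment_duration_s: float,
    window_s: float = 10.0,
    overlap_s: float = 8.0,
    count_mode: str = "formula",
    clip_s: float | None = None,
) -> list[tuple[float, float]]:
    """Sliding-window spans over one state segment.

    stride = window − overlap.  In ``formula`` mode the number of windows is
    ``floor(segment / stride)`` — the bookkeeping that yields 150 windows for
    a 5-min segment at 10 s / 8 s — with starts at 0, stride, 2·stride, …;
    trailing windows are truncated at *clip_s* (the end of the available
    recording, by default the segment end).  In ``strict`` mode only fully
    contained windows are produced: ``floor((segment − window)/stride) + 1``.
    """
    if window_s <= overlap_s or overlap_s < 0:
        raise ConfigError("require window_s > overlap_s >= 0")
    if segment_duration_s < window_s:
        raise ConfigError("segment shorter than one window")
    stride = window_s - overlap_s
    clip = segment_duration_s if clip_s is None else clip_s
    if count_mode == "formula":
        count = int(np.floor(segment_duration_s / stride + 1e-9))
    elif count_mode == "strict":
        count = int(np.floor((segment_duration_s - window_s) / stride + 1e-9)) + 1
    else:
        raise ConfigError(f"unknown count_mode {count_mode!r}")
    spans = []
    for i in range(count):
        start = i * stride
        end = min(start + window_s, clip)
        if end > start:
            spans.append((start, end))
    return spans


def _aggregate(cycle_features: list[dict[str, float]]) -> dict[str, float]:
    return {
        name: float(np.mean([cf[name] for cf in cycle_features]))
        for name in FEATURE_NAMES
    }


def build_dataset(
    cohort,
    params: ExtractionParams | None = None,
) -> list[WindowSample]:
    """Segment, featurize and window a labeled cohort.

    *cohort* is a sequence of ``(participant_id, state_label, recording)``
    triples, one non-fatigue and one fatigue segment per participant.  Each
    window aggregates (arithmetic mean) the per-cycle feature vectors of all
    cycles whose heel strike lies inside the window; windows with fewer than
    ``min_cycles_per_window`` complete cycles are dropped with a logged
    count, and a participant segment yielding zero windows is excluded with
    a warning.
    """
    params = params or ExtractionParams()
    samples: list[WindowSample] = []
    for participant_id, state_label, rec in cohort:
        cycles = segment_recording(
            rec,
            threshold_N=params.cycle_threshold_N,
            min_stance_s=params.min_stance_s,
            min_swing_s=params.min_swing_s,
        )
        feats = [extract_cycle_features(rec, c, params) for c in cycles]
        hs_times = np.array([c.hs_index for c in cycles], dtype=float) / rec.fs
        nominal = params.segment_duration_s
        if nominal is None:
            nominal = float(rec.metadata.get("segment_duration_s", rec.duration_s))
        spans = make_windows(
            nominal,
            params.window_s,
            params.overlap_s,
            params.count_mode,
            clip_s=rec.duration_s,
        )
        dropped = 0
        produced = 0
        for start, end in spans:
            in_win = np.flatnonzero((hs_times >= start) & (hs_times < end))
            if in_win.shape[0] < params.min_cycles_per_window:
                dropped += 1
                continue
            samples.append(
                WindowSample(
                    participant_id=participant_id,
                    state_label=state_label,
                    window_start_s=float(start),
                    n_cycles=int(in_win.shape[0]),
                    features=_aggregate([feats[i] for i in in_win]),
                )
            )
            produced += 1
        if dropped:
            logger.info(
                "%s/%s: dropped %d window(s) with < %d cycles",
                participant_id, state_label, dropped, params.min_cycles_per_window,
            )
        if produced == 0:
            logger.warning(
                "%s/%s: no valid windows, participant segment excluded",
                participant_id, state_label,
            )
    return samples
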