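"""Synthetic gait recordings with known ground truth.

The simulator emulates a treadmill walk recorded by a 7-region plantar
force insole plus a heel-mounted 9-axis IMU at 110 Hz.  Each gait cycle is
built from closed-form phase waveforms:

* regional forces are raised-cosine bumps inside per-region activation
  windows, scaled to the region's peak force — smooth, integrable in closed
  form, with the small arch sensors calibrated to carry roughly 1 N·s of
  impulse per cycle;
* rotation angles are piecewise-smooth with an exact plateau over the
  15–25% flat-foot span, so the flat-foot quiescence assumption holds in
  ground truth by construction;
* angular velocities are the analytic derivatives of the angle trajectories
  plus a fine swing-phase oscillation ("tremor") that controls the
  variability of the resultant angular acceleration;
* sensor noise is additive Gaussian per channel, and a slow linear drift is
  added to the transverse angle to exercise the flat-foot re-referencing.

Fatigue is injected by deforming the template in the directions reported
for fatigued gait: increased medial/lateral arch impulse, increased
sagittal maximum angle and rotation range, and decreased variability of the
resultant angular acceleration.  For force and angle features the injected
multiplicative shift is exact before noise (the features are homogeneous in
the scaled amplitudes); the angular-acceleration CV shift is directional,
implemented by scaling the tremor amplitude.

Alongside every recording the simulator emits a per-cycle ground-truth
feature table computed from the clean (noise-free) signals by direct,
self-contained formulas, so downstream segmentation and feature extraction
can be checked against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ConfigError, FORCE_REGIONS, SensorRecording
from .features import FEATURE_NAMES, WindowSample

__all__ = [
    "GaitTemplate",
    "FatigueEffectSpec",
    "NoiseSpec",
    "CohortConfig",
    "SimulatedParticipant",
    "simulate_recording",
    "simulate_cohort",
    "simulate_feature_cohort",
    "cohort_to_triples",
    "apply_effects",
]

STATES = ("non_fatigue", "fatigue")

#: The five characteristics shifted by fatigue (injection defaults).
DEFAULT_EFFECT_FEATURES = (
    "Imp_MA", "Imp_LA", "theta_Sag_Max", "theta_Sag_Ran", "alpha_Res_CV",
)


def _bump(p: np.ndarray, a: float, b: float) -> np.ndarray:
    """Raised-cosine bump on phase window [a, b): 0 at the edges, 1 mid-window."""
    out = np.zeros_like(p)
    m = (p >= a) & (p < b)
    out[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (p[m] - a) / (b - a)))
    return out


def _dbump(p: np.ndarray, a: float, b: float) -> np.ndarray:
    """Phase-derivative of :func:`_bump` (per unit phase)."""
    out = np.zeros_like(p)
    m = (p >= a) & (p < b)
    w = b - a
    out[m] = 0.5 * (2.0 * np.pi / w) * np.sin(2.0 * np.pi * (p[m] - a) / w)
    return out


@dataclass
class GaitTemplate:
    """Closed-form per-cycle waveform parameters for one walker.

    Defaults describe an older adult walking briskly: 1.1-s cycles, stance
    ~62% of the cycle, heel-dominant loading, ~22 deg sagittal swing
    excursion.  Activation windows are (start, end) fractions of the cycle.
    """

    cycle_duration_s: float = 1.1
    stance_fraction: float = 0.62
    region_peak_forces_N: dict[str, float] = field(
        default_factory=lambda: {
            "Hx": 25.0, "MM": 35.0, "POF": 30.0, "LM": 30.0,
            "MA": 5.4, "LA": 5.6, "H": 60.0,
        }
    )
    region_activation_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "H": (0.00, 0.30), "MA": (0.15, 0.50), "LA": (0.18, 0.52),
            "POF": (0.20, 0.55), "MM": (0.25, 0.60), "LM": (0.25, 0.58),
            "Hx": (0.35, 0.62),
        }
    )
    # angle amplitudes (deg); plateau over [0.10, 0.55] covers the flat span
    sag_swing_amp_deg: float = 22.0
    sag_dip_amp_deg: float = 8.0
    cor_swing_amp_deg: float = 6.0
    cor_dip_amp_deg: float = 2.0
    tra_swing_amp_deg: float = 8.0
    # acceleration bump amplitudes (m/s^2)
    acc_impact_amp: float = 8.0
    acc_swing_amp: float = 3.0
    # swing-phase gyro tremor: amplitude (deg/s) and oscillations per cycle
    tremor_amp_dps: float = 15.0
    tremor_cycles: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ConfigError("stance_fraction must lie in (0, 1)")
        if self.cycle_duration_s <= 0:
            raise ConfigError("cycle_duration_s must be positive")
        for r, (a, b) in self.region_activation_windows.items():
            if not (0.0 <= a < b <= 1.0):
                raise ConfigError(f"activation window of {r} outside [0, 1]")

    def samples_per_cycle(self, fs: float) -> int:
        return max(2, int(round(self.cycle_duration_s * fs)))


@dataclass
class FatigueEffectSpec:
    """Multiplicative per-feature shifts applied in the fatigue state.

    Keys name the feature whose ground truth should shift; the simulator
    maps each onto the template parameter that produces it:

    * ``Imp_MA`` / ``Imp_LA`` — medial/lateral arch peak force (exact shift);
    * ``theta_Sag_Max`` / ``theta_Sag_Ran`` — all sagittal angle amplitudes
      (exact shift; the two factors must agree as they share one knob);
    * ``alpha_Res_CV`` — tremor amplitude (directional: a factor < 1 lowers
      the angular-acceleration CV, the exact magnitude is waveform-dependent).
    """

    factors: dict[str, float] = field(
        default_factory=lambda: {
            "Imp_MA": 1.30,
            "Imp_LA": 1.30,
            "theta_Sag_Max": 1.20,
            "theta_Sag_Ran": 1.20,
            "alpha_Res_CV": 0.70,
        }
    )

    def __post_init__(self) -> None:
        known = set(DEFAULT_EFFECT_FEATURES)
        for k, v in self.factors.items():
            if k not in known:
                raise ConfigError(f"no template mapping for effect on {k!r}")
            if not math.isfinite(v) or v <= 0:
                raise ConfigError(f"effect factor for {k} must be finite > 0")
        f_max = self.factors.get("theta_Sag_Max")
        f_ran = self.factors.get("theta_Sag_Ran")
        if f_max is not None and f_ran is not None and f_max != f_ran:
            raise ConfigError(
                "theta_Sag_Max and theta_Sag_Ran share the sagittal amplitude "
                "knob; their factors must agree"
            )


def apply_effects(template: GaitTemplate, effects: FatigueEffectSpec) -> GaitTemplate:
    """Return the fatigue-state template implied by *effects*."""
    peaks = dict(template.region_peak_forces_N)
    kw: dict[str, object] = {}
    f = effects.factors
    if "Imp_MA" in f:
        peaks["MA"] = peaks["MA"] * f["Imp_MA"]
    if "Imp_LA" in f:
        peaks["LA"] = peaks["LA"] * f["Imp_LA"]
    sag = f.get("theta_Sag_Max", f.get("theta_Sag_Ran"))
    if sag is not None:
        kw["sag_swing_amp_deg"] = template.sag_swing_amp_deg * sag
        kw["sag_dip_amp_deg"] = template.sag_dip_amp_deg * sag
    if "alpha_Res_CV" in f:
        # the oscillation amplitude floors the resultant angular
        # acceleration, so CV moves inversely with it (directional mapping)
        kw["tremor_amp_dps"] = template.tremor_amp_dps / f["alpha_Res_CV"]
    return replace(template, region_peak_forces_N=peaks, **kw)


@dataclass
class NoiseSpec:
    """Per-channel additive Gaussian noise SDs and transverse-angle drift."""

    force_N: float = 0.5
    acc_ms2: float = 0.15
    gyr_dps: float = 2.0
    ang_deg: float = 0.25
    drift_deg_per_s: float = 0.05

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class CohortConfig:
    """Study-design parameters for a simulated cohort.

    Defaults mirror the study conditions: 18 participants, one 5-min
    segment per state.  ``pad_s`` extends each simulated segment by one
    window length of extra cycles, standing in for the continuation of the
    60-min recording from which the real 5-min segments are cut, so that
    trailing sliding windows are backed by full data.
    """

    n_participants: int = 18
    segment_duration_s: float = 300.0
    pad_s: float = 10.0
    seed: int = 0
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: {
            "peaks": 0.10,          # multiplicative SD on region peak forces
            "amplitudes": 0.10,     # multiplicative SD on angle/acc amplitudes
            "tremor": 0.10,         # multiplicative SD on tremor amplitude
            "cycle_duration_s": 0.05,  # additive SD (s) on cycle duration
        }
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.segment_duration_s < 10.0:
            raise ConfigError("segments must hold at least one 10-s window")


@dataclass
class SimulatedParticipant:
    participant_id: str
    template: GaitTemplate
    recordings: dict[str, SensorRecording]
    truths: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# clean waveform synthesis

def _clean_signals(
    template: GaitTemplate, n_samples: int, fs: float, drift_deg_per_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free (force, acc, gyr, ang) arrays for *n_samples* samples."""
    L = template.samples_per_cycle(fs)
    i = np.arange(n_samples)
    p = (i % L) / L
    t = i / fs
    T = L / fs  # effective cycle duration after rounding to whole samples

    force = np.zeros((n_samples, 7))
    for j, r in enumerate(FORCE_REGIONS):
        a, b = template.region_activation_windows[r]
        force[:, j] = template.region_peak_forces_N[r] * _bump(p, a, b)

    sag = (
        -template.sag_dip_amp_deg * _bump(p, 0.0, 0.10)
        + template.sag_swing_amp_deg * _bump(p, 0.55, 1.0)
    )
    cor = (
        -template.cor_dip_amp_deg * _bump(p, 0.0, 0.10)
        + template.cor_swing_amp_deg * _bump(p, 0.55, 1.0)
    )
    tra = template.tra_swing_amp_deg * _bump(p, 0.60, 1.0)
    ang = np.column_stack([sag, cor, tra + drift_deg_per_s * t])

    # angular velocity: analytic d(angle)/dt plus swing tremor
    dsag = (
        -template.sag_dip_amp_deg * _dbump(p, 0.0, 0.10)
        + template.sag_swing_amp_deg * _dbump(p, 0.55, 1.0)
    ) / T
    dcor = (
        -template.cor_dip_amp_deg * _dbump(p, 0.0, 0.10)
        + template.cor_swing_amp_deg * _dbump(p, 0.55, 1.0)
    ) / T
    dtra = template.tra_swing_amp_deg * _dbump(p, 0.60, 1.0) / T
    # three-phase oscillatory component: with the axes phased 120 deg apart
    # the oscillation alone has a constant resultant magnitude, so its
    # amplitude sets a floor under the resultant angular acceleration —
    # raising it provably lowers the angular-acceleration CV (and vice
    # versa), which is how the fatigue effect on that CV is injected.
    m = template.tremor_cycles
    tr = template.tremor_amp_dps
    gyr = np.column_stack(
        [
            dsag + tr * np.sin(2 * np.pi * m * p),
            dcor + tr * np.sin(2 * np.pi * m * p + 2 * np.pi / 3),
            dtra + tr * np.sin(2 * np.pi * m * p + 4 * np.pi / 3),
        ]
    )

    g = 9.81
    acc = np.column_stack(
        [
            template.acc_impact_amp * _bump(p, 0.0, 0.08)
            + template.acc_swing_amp * _bump(p, 0.60, 0.95),
            0.5 * template.acc_swing_amp * _bump(p, 0.58, 0.95),
            g + 2.5 * _bump(p, 0.02, 0.10) - 2.0 * _bump(p, 0.60, 0.90),
        ]
    )
    return force, acc, gyr, ang


# ---------------------------------------------------------------------------
# ground-truth features (self-contained re-statement of the definitions)

def _truth_cycles(
    total_clean: np.ndarray, threshold: float, min_swing_samples: int
) -> list[tuple[int, int, int]]:
    """Complete (hs, to, next_hs) triples from a clean total-force series."""
    above = total_clean >= threshold
    flips = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate(([0], flips + 1))
    hs: list[int] = []
    for k in range(1, starts.shape[0]):
        s = int(starts[k])
        if above[s] and (s - int(starts[k - 1])) >= min_swing_samples:
            hs.append(s)
    falls = np.flatnonzero(np.diff(above.astype(np.int8)) == -1) + 1
    out = []
    for k in range(len(hs) - 1):
        to = int(falls[(falls > hs[k]) & (falls < hs[k + 1])][0])
        out.append((hs[k], to, hs[k + 1]))
    return out


def _truth_features_one_cycle(
    force: np.ndarray,
    acc: np.ndarray,
    gyr: np.ndarray,
    ang: np.ndarray,
    hs: int,
    next_hs: int,
    fs: float,
    region_threshold: float,
) -> dict[str, float]:
    out: dict[str, float] = {}
    fslice = force[hs:next_hs]
    for j, r in enumerate(FORCE_REGIONS):
        f = fslice[:, j]
        mask = f >= region_threshold
        out[f"PF_{r}"] = float(f.max())
        if not mask.any():
            out[f"CT_{r}"] = 0.0
            out[f"Imp_{r}"] = 0.0
            out[f"FCV_{r}"] = 0.0
            continue
        out[f"CT_{r}"] = float(mask.sum()) / fs
        out[f"Imp_{r}"] = float(f[mask].sum()) / fs
        sel = f[mask]
        out[f"FCV_{r}"] = (
            float(np.std(sel, ddof=1) / abs(sel.mean())) if sel.size >= 2 else 0.0
        )

    def stats(x: np.ndarray, prefix: str) -> None:
        out[f"{prefix}_Max"] = float(x.max())
        out[f"{prefix}_RMS"] = float(np.sqrt(np.mean(x * x)))
        m = abs(float(x.mean()))
        out[f"{prefix}_CV"] = float(np.std(x, ddof=1)) / m if m >= 1e-9 else 0.0

    a = acc[hs:next_hs]
    w = gyr[hs:next_hs]
    stats(np.linalg.norm(a, axis=1), "acc_Res")
    stats(np.linalg.norm(np.gradient(a, axis=0) * fs, axis=1), "j_Res")
    stats(np.linalg.norm(w, axis=1), "w_Res")
    stats(np.linalg.norm(np.gradient(w, axis=0) * fs, axis=1), "alpha_Res")

    length = next_hs - hs
    fl_s = hs + int(np.floor(0.15 * length + 0.5))
    fl_e = hs + int(np.floor(0.25 * length + 0.5))
    for j, plane in enumerate(("Sag", "Cor", "Tra")):
        th = ang[hs:next_hs, j] - ang[fl_s:fl_e, j].mean()
        out[f"theta_{plane}_Max"] = float(th.max())
        out[f"theta_{plane}_Ran"] = float(th.max() - th.min())
        m = abs(float(th.mean()))
        out[f"theta_{plane}_CV"] = float(np.std(th, ddof=1)) / m if m >= 1e-9 else 0.0
    return out


def _ground_truth_table(
    force: np.ndarray,
    acc: np.ndarray,
    gyr: np.ndarray,
    ang: np.ndarray,
    fs: float,
    cycle_threshold: float = 10.0,
    region_threshold: float = 1.0,
    min_swing_s: float = 0.1,
) -> pd.DataFrame:
    """Per-cycle ground-truth features from clean signals."""
    spans = _truth_cycles(
        force.sum(axis=1), cycle_threshold, int(np.ceil(min_swing_s * fs))
    )
    rows = []
    for hs, to, next_hs in spans:
        row = {"hs_index": hs, "to_index": to, "next_hs_index": next_hs}
        row.update(
            _truth_features_one_cycle(
                force, acc, gyr, ang, hs, next_hs, fs, region_threshold
            )
        )
        rows.append(row)
    cols = ["hs_index", "to_index", "next_hs_index", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# public simulation entry points

def simulate_recording(
    template: GaitTemplate,
    state: str,
    effects: FatigueEffectSpec | None = None,
    duration_s: float = 300.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    fs: float = 110.0,
    participant_id: str = "sim",
    compute_truth: bool = True,
) -> tuple[SensorRecording, pd.DataFrame | None]:
    """Simulate one state segment; return (recording, per-cycle ground truth).

    The duration is rounded up to a whole number of cycles.  In the
    ``fatigue`` state the template is first deformed by *effects*.  Ground
    truth is computed from the clean signals (drift included, noise
    excluded); identical seeds give identical output.
    """
    if state not in STATES:
        raise ConfigError(f"state must be one of {STATES}")
    if duration_s < template.cycle_duration_s:
        raise ConfigError("duration shorter than one gait cycle")
    noise = noise if noise is not None else NoiseSpec()
    if state == "fatigue":
        template = apply_effects(template, effects or FatigueEffectSpec())

    L = template.samples_per_cycle(fs)
    n_cycles = int(np.ceil(duration_s * fs / L))
    n = n_cycles * L
    force, acc, gyr, ang = _clean_signals(template, n, fs, noise.drift_deg_per_s)

    truth = None
    if compute_truth:
        truth = _ground_truth_table(force, acc, gyr, ang, fs)

    rng = np.random.default_rng(seed)
    if noise.force_N > 0:
        force = np.clip(force + rng.normal(0, noise.force_N, force.shape), 0, None)
    if noise.acc_ms2 > 0:
        acc = acc + rng.normal(0, noise.acc_ms2, acc.shape)
    if noise.gyr_dps > 0:
        gyr = gyr + rng.normal(0, noise.gyr_dps, gyr.shape)
    if noise.ang_deg > 0:
        ang = ang + rng.normal(0, noise.ang_deg, ang.shape)

    rec = SensorRecording(
        participant_id=participant_id,
        timestamps=np.arange(n) / fs,
        force=force,
        acc=acc,
        gyr=gyr,
        ang=ang,
        metadata={"state": state, "seed": seed},
    )
    return rec, truth


def _perturbed_template(
    base: GaitTemplate, sd: dict[str, float], rng: np.random.Generator
) -> GaitTemplate:
    """Draw one participant's template from between-subject dispersions."""
    s_peak = sd.get("peaks", 0.0)
    s_amp = sd.get("amplitudes", 0.0)
    s_trem = sd.get("tremor", 0.0)
    s_cyc = sd.get("cycle_duration_s", 0.0)

    def mult(s: float) -> float:
        return float(np.clip(rng.normal(1.0, s), 0.5, 1.5)) if s > 0 else 1.0

    peaks = {r: v * mult(s_peak) for r, v in base.region_peak_forces_N.items()}
    amp = mult(s_amp)
    return replace(
        base,
        cycle_duration_s=float(
            np.clip(base.cycle_duration_s + rng.normal(0.0, s_cyc), 0.7, 1.6)
        )
        if s_cyc > 0
        else base.cycle_duration_s,
        region_peak_forces_N=peaks,
        sag_swing_amp_deg=base.sag_swing_amp_deg * amp,
        sag_dip_amp_deg=base.sag_dip_amp_deg * amp,
        cor_swing_amp_deg=base.cor_swing_amp_deg * mult(s_amp),
        tra_swing_amp_deg=base.tra_swing_amp_deg * mult(s_amp),
        acc_impact_amp=base.acc_impact_amp * mult(s_amp),
        tremor_amp_dps=base.tremor_amp_dps * mult(s_trem),
    )


def simulate_cohort(
    cfg: CohortConfig | None = None,
    effects: FatigueEffectSpec | None = None,
    template: GaitTemplate | None = None,
    compute_truth: bool = True,
) -> list[SimulatedParticipant]:
    """Simulate paired (non-fatigue, fatigue) segments for a whole cohort.

    Per-participant templates are drawn from the cohort's between-subject
    dispersions; all randomness derives from the single cohort seed through
    deterministic substreams, so identical configs give identical cohorts.
    """
    cfg = cfg or CohortConfig()
    effects = effects or FatigueEffectSpec()
    base = template or GaitTemplate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants)
    duration = cfg.segment_duration_s + cfg.pad_s

    participants: list[SimulatedParticipant] = []
    for j, child in enumerate(children):
        sub = child.spawn(3)
        rng_t = np.random.default_rng(sub[0])
        tpl = _perturbed_template(base, cfg.between_subject_sd, rng_t)
        pid = f"P{j + 1:02d}"
        recordings: dict[str, SensorRecording] = {}
        truths: dict[str, pd.DataFrame] = {}
        for state, stream in zip(STATES, (sub[1], sub[2])):
            seed = int(stream.generate_state(1)[0] % (2**31))
            rec, truth = simulate_recording(
                tpl,
                state,
                effects,
                duration_s=duration,
                noise=cfg.noise,
                seed=seed,
                participant_id=pid,
                compute_truth=compute_truth,
            )
            rec.metadata["segment_duration_s"] = cfg.segment_duration_s
            recordings[state] = rec
            truths[state] = truth
        participants.append(SimulatedParticipant(pid, tpl, recordings, truths))
    return participants


def cohort_to_triples(participants: list[SimulatedParticipant]):
    """Flatten a simulated cohort into (participant, state, recording) triples."""
    return [
        (p.participant_id, state, p.recordings[state])
        for p in participants
        for state in STATES
    ]


def simulate_feature_cohort(
    n_participants: int = 18,
    windows_per_state: int = 150,
    effect_d: float = 2.0,
    within_sd: float = 1.0,
    between_sd: float = 0.25,
    informative: tuple[str, ...] = DEFAULT_EFFECT_FEATURES,
    seed: int = 0,
) -> list[WindowSample]:
    """Window samples drawn directly in feature space.

    Every feature is Gaussian: a per-participant baseline (SD *between_sd*)
    plus within-participant noise (SD *within_sd*).  Exactly the
    *informative* features receive a fatigue-state mean shift of
    ``effect_d * sqrt(within_sd² + between_sd²)`` — i.e. a standardized
    separation of *effect_d* on the pooled sample — signed negatively for
    CV-type features (fatigue lowers them) and positively otherwise.  This
    abstraction from the signal level gives exact control over which and
    how many features carry information, which the waveform simulator
    cannot (it co-moves correlated features).
    """
    unknown = set(informative) - set(FEATURE_NAMES)
    if unknown:
        raise ConfigError(f"unknown feature name(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    shift = effect_d * math.sqrt(within_sd**2 + between_sd**2)
    signs = {name: (-1.0 if name.endswith("_CV") else 1.0) for name in informative}
    samples: list[WindowSample] = []
    n_feat = len(FEATURE_NAMES)
    for j in range(n_participants):
        pid = f"P{j + 1:02d}"
        baseline = rng.normal(0.0, between_sd, n_feat)
        for state in STATES:
            values = baseline + rng.normal(
                0.0, within_sd, (windows_per_state, n_feat)
            )
            if state == "fatigue":
                for name in informative:
                    k = FEATURE_NAMES.index(name)
                    values[:, k] += signs[name] * shift
            for w in range(windows_per_state):
                samples.append(
                    WindowSample(
                        participant_id=pid,
                        state_label=state,
                        window_start_s=2.0 * w,
                        n_cycles=5,
                        features=dict(zip(FEATURE_NAMES, values[w])),
                    )
                )
    return samples
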