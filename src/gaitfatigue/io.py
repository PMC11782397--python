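"""Reading and writing sensor recordings and feature tables.

The on-disk exchange format is deliberately plain: comma-separated UTF-8
text with a single header row, "." decimal, one row per sample.  Units are
fixed by the channel schema (N, m/s^2, deg/s, deg) and never guessed from
the file.  Timestamps are optional on ingest and reconstructed as ``i / fs``
when absent, because the device streams at a fixed rate and logs may omit
time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FORCE_REGIONS",
    "IMU_CHANNELS",
    "ChannelSchema",
    "SensorRecording",
    "SchemaError",
    "IngestError",
    "ContractError",
    "ConfigError",
    "read_recording",
    "write_recording",
    "write_feature_table",
    "read_feature_table",
]

#: Plantar force regions, in canonical order: hallux, medial metatarsal,
#: posterior of footpad, lateral metatarsal, medial arch, lateral arch, heel.
FORCE_REGIONS: tuple[str, ...] = ("Hx", "MM", "POF", "LM", "MA", "LA", "H")

#: IMU channels: triaxial acceleration (m/s^2), angular velocity (deg/s),
#: and rotation angle (deg) in the sagittal/coronal/transverse planes.
IMU_CHANNELS: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "ang_sag", "ang_cor", "ang_tra",
)

TIME_COLUMN = "time"


class SchemaError(ValueError):
    """A file does not conform to the channel schema."""


class IngestError(ValueError):
    """A file is schema-conformant but its values are physically invalid."""


class ContractError(ValueError):
    """An in-memory object violates a documented precondition."""


class ConfigError(ValueError):
    """A configuration value violates a documented precondition."""


@dataclass(frozen=True)
class ChannelSchema:
    """Channel naming, ordering and sampling-rate contract.

    All modules share one schema instance so that column order in files,
    array column order in memory, and feature naming stay consistent.
    """

    force_regions: tuple[str, ...] = FORCE_REGIONS
    imu_channels: tuple[str, ...] = IMU_CHANNELS
    sampling_rate_hz: float = 110.0

    def __post_init__(self) -> None:
        if len(self.force_regions) != 7:
            raise SchemaError("schema requires exactly 7 force regions")
        if len(self.imu_channels) != 9:
            raise SchemaError("schema requires exactly 9 IMU channels")
        if not self.sampling_rate_hz > 0:
            raise SchemaError("sampling_rate_hz must be positive")

    @property
    def data_columns(self) -> tuple[str, ...]:
        return tuple(self.force_regions) + tuple(self.imu_channels)


DEFAULT_SCHEMA = ChannelSchema()


@dataclass
class SensorRecording:
    """Synchronised multi-channel time series for one participant/session.

    Arrays are float64 with one row per sample: ``force`` is (n, 7) in N,
    ``acc`` (n, 3) in m/s^2, ``gyr`` (n, 3) in deg/s, ``ang`` (n, 3) in deg
    (sagittal, coronal, transverse).  ``timestamps`` is seconds, uniformly
    spaced at 1/fs.
    """

    participant_id: str
    timestamps: np.ndarray
    force: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    ang: np.ndarray
    schema: ChannelSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        self.ang = np.asarray(self.ang, dtype=float)
        n = self.timestamps.shape[0]
        if n < 2:
            raise ContractError("recording must have at least 2 samples")
        for name, arr, width in (
            ("force", self.force, 7), ("acc", self.acc, 3),
            ("gyr", self.gyr, 3), ("ang", self.ang, 3),
        ):
            if arr.shape != (n, width):
                raise ContractError(
                    f"{name} must have shape ({n}, {width}), got {arr.shape}"
                )
            if np.isnan(arr).any():
                raise IngestError(f"{name} contains missing samples")
        if np.isnan(self.timestamps).any():
            raise IngestError("timestamps contain missing samples")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise IngestError("timestamps must be strictly increasing")
        neg = np.argwhere(self.force < 0)
        if neg.size:
            row = int(neg[0, 0])
            raise IngestError(f"negative force at row {row}")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def fs(self) -> float:
        return float(self.schema.sampling_rate_hz)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_frame(self) -> pd.DataFrame:
        data = {TIME_COLUMN: self.timestamps}
        for j, r in enumerate(self.schema.force_regions):
            data[r] = self.force[:, j]
        imu = np.hstack([self.acc, self.gyr, self.ang])
        for j, c in enumerate(self.schema.imu_channels):
            data[c] = imu[:, j]
        return pd.DataFrame(data)


def read_recording(
    path: str | Path,
    schema: ChannelSchema = DEFAULT_SCHEMA,
    participant_id: str | None = None,
) -> SensorRecording:
    """Read one CSV recording and validate it against *schema*.

    The file must carry a header row naming every channel column; a ``time``
    column is optional and reconstructed as ``i / fs`` when absent.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema.data_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    n = len(df)
    if TIME_COLUMN in df.columns:
        t = df[TIME_COLUMN].to_numpy(dtype=float)
    else:
        t = np.arange(n, dtype=float) / schema.sampling_rate_hz
    force = df[list(schema.force_regions)].to_numpy(dtype=float)
    imu = df[list(schema.imu_channels)].to_numpy(dtype=float)
    return SensorRecording(
        participant_id=participant_id or path.stem,
        timestamps=t,
        force=force,
        acc=imu[:, 0:3],
        gyr=imu[:, 3:6],
        ang=imu[:, 6:9],
        schema=schema,
    )


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    """Write *rec* as CSV, round-trippable at full float precision."""
    path = Path(path)
    # %.17g guarantees bit-identical float64 round trips
    rec.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# feature tables

def feature_table_columns(feature_names: Sequence[str]) -> list[str]:
    return ["participant_id", "window_start_s", "state_label", *feature_names]


def write_feature_table(samples, path: str | Path, feature_names=None) -> None:
    """Write window samples as a CSV feature table.

    One row per window; columns are participant_id, window_start_s,
    state_label, then the 49 features in canonical order.  All samples must
    share one feature-name set.
    """
    from .features import FEATURE_NAMES  # canonical order; avoid cycle at import

    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    rows = []
    for s in samples:
        if set(s.features.keys()) != set(names):
            raise ContractError(
                f"window sample for {s.participant_id} has an inconsistent "
                f"feature set"
            )
        rows.append(
            {
                "participant_id": s.participant_id,
                "window_start_s": s.window_start_s,
                "state_label": s.state_label,
                **{k: s.features[k] for k in names},
            }
        )
    df = pd.DataFrame(rows, columns=feature_table_columns(names))
    df.to_csv(Path(path), index=False, float_format="%.17g")


def read_feature_table(path: str | Path):
    """Read a feature-table CSV back into WindowSample objects."""
    from .features import FEATURE_NAMES, WindowSample

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in feature_table_columns(FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {', '.join(missing)}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            WindowSample(
                participant_id=str(row["participant_id"]),
                state_label=str(row["state_label"]),
                window_start_s=float(row["window_start_s"]),
                n_cycles=0,
                features={k: float(row[k]) for k in FEATURE_NAMES},
            )
        )
    return samples
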