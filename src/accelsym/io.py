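"""Reading, validation, trimming and channel reduction of accelerometer recordings.

Recording files are delimited text (comma or tab, autodetected; gzip
accepted) with a header row and columns ``time_s, ax, ay, az``.  Times are
seconds, accelerations m/s²; no unit conversion is performed.  After loading,
samples live on a uniform 1/fs grid: recordings whose timestamp jitter
exceeds 1 % of the sample period are linearly interpolated onto that grid,
because the downstream DFT assumes uniform sampling.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AccelRecording",
    "LoadError",
    "DEFAULT_SCHEMA",
    "read_recording",
    "write_recording",
    "read_manifest",
    "scan_recording_directory",
    "trim",
    "magnitude",
    "channel",
]

#: Default column mapping: logical name -> column header in the file.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "time": "time_s",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
}

#: Relative timestamp jitter above which a recording is resampled.
JITTER_TOL = 0.01


class LoadError(ValueError):
    """A recording file failed validation (missing column, NaN, bad time axis)."""


@dataclasses.dataclass
class AccelRecording:
    """One body side's 3-axis acceleration trace on a uniform time grid.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing, uniform spacing 1/fs.
    a : ndarray, shape (n, 3)
        Acceleration samples (m/s²), columns x, y, z.
    fs : float
        Sampling rate in Hz.
    side : str
        ``"L"`` or ``"R"``.
    exercise_id, individual_id : str
        Labels used for aggregation tables (exercises ``E1``..``E8``).
    meta : dict
        Optional participant metadata (age, gender, height_cm, bmi).
    """

    t: np.ndarray
    a: np.ndarray
    fs: float
    side: str = "L"
    exercise_id: str = ""
    individual_id: str = ""
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError(f"a must be (n, 3), got {self.a.shape}")
        if len(self.t) != len(self.a):
            raise ValueError(
                f"t has {len(self.t)} samples but a has {len(self.a)} rows"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Record length in seconds (n/fs, i.e. including the last sample's dwell)."""
        return self.n_samples / self.fs


def _autodetect_read(path: str | Path) -> pd.DataFrame:
    # sniff comma vs tab from the header line; the C parser with
    # float_precision="round_trip" keeps write→read lossless
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_recording(
    path: str | Path,
    schema: Mapping[str, str] = DEFAULT_SCHEMA,
    *,
    side: str = "L",
    exercise_id: str = "",
    individual_id: str = "",
    meta: dict | None = None,
) -> AccelRecording:
    """Load and validate one recording file.

    Raises :class:`LoadError` naming the offending row/column for missing
    columns, NaN samples or a non-monotone time axis.  Timestamp jitter above
    1 % of the nominal sample period triggers linear-interpolation resampling
    onto the uniform grid.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"recording file not found: {path}")
    df = _autodetect_read(path)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if len(df) < 2:
        raise LoadError(f"{path}: need at least 2 sample rows, got {len(df)}")

    cols = [schema["time"], schema["ax"], schema["ay"], schema["az"]]
    sub = df[cols].astype(float)
    if sub.isna().any().any():
        row = int(sub.isna().any(axis=1).idxmax())
        col = sub.columns[sub.isna().any()][0]
        raise LoadError(f"{path}: NaN sample at row {row}, column {col!r}")

    t = sub[cols[0]].to_numpy()
    a = sub[cols[1:]].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise LoadError(f"{path}: time not strictly increasing at row {row}")

    period = float(np.median(dt))
    fs = 1.0 / period
    # snap to an integer rate when within jitter of one (100 Hz nominal)
    if abs(fs - round(fs)) / fs < JITTER_TOL:
        fs = float(round(fs))
    if np.max(np.abs(dt - 1.0 / fs)) > JITTER_TOL / fs:
        t, a = _resample_uniform(t, a, fs)
    else:
        t = t[0] + np.arange(len(t)) / fs

    return AccelRecording(
        t=t,
        a=a,
        fs=fs,
        side=side,
        exercise_id=exercise_id,
        individual_id=individual_id,
        meta=dict(meta or {}),
    )


def _resample_uniform(t: np.ndarray, a: np.ndarray, fs: float):
    """Linear interpolation onto a uniform 1/fs grid spanning [t0, t_end]."""
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    out = np.column_stack([np.interp(grid, t, a[:, j]) for j in range(a.shape[1])])
    return grid, out


def write_recording(rec: AccelRecording, path: str | Path) -> None:
    """Write a recording in the delimited-text format read_recording consumes.

    Values are written with float round-trip precision so
    ``read_recording(write_recording(rec))`` reproduces samples exactly.
    """
    df = pd.DataFrame(
        {
            "time_s": rec.t,
            "ax": rec.a[:, 0],
            "ay": rec.a[:, 1],
            "az": rec.a[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


MANIFEST_COLUMNS = ["individual_id", "exercise_id", "side", "path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: individual_id, exercise_id, side, path.  Optional
    participant columns (age, gender, height_cm, bmi) are passed through.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"manifest {path}: missing column(s) {missing}")
    bad = ~df["side"].isin(["L", "R"])
    if bad.any():
        raise LoadError(
            f"manifest {path}: invalid side value(s) {df.loc[bad, 'side'].unique().tolist()}"
        )
    return df


def scan_recording_directory(root: str | Path, pattern: str = "*.csv") -> pd.DataFrame:
    """Best-effort manifest builder for a directory of recording files.

    Expects file names ``<individual>_<exercise>_<side>.csv`` (side L/R).
    This adapter is isolated here so a different deposit layout only requires
    changing this function; files that do not match the pattern are skipped
    with a warning.  Disabled by default in the pipeline (explicit call only).
    """
    rows = []
    for p in sorted(Path(root).rglob(pattern)):
        parts = p.stem.split("_")
        if len(parts) < 3 or parts[-1] not in ("L", "R"):
            warnings.warn(f"skipping unrecognized file name: {p.name}")
            continue
        rows.append(
            {
                "individual_id": "_".join(parts[:-2]),
                "exercise_id": parts[-2],
                "side": parts[-1],
                "path": str(p),
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def trim(rec: AccelRecording, head_s: float = 1.0, tail_s: float = 1.0) -> AccelRecording:
    """Drop the first ``head_s`` and last ``tail_s`` seconds; re-zero times.

    The start and end of a record typically contain handling artefacts
    (placing/removing the phone), so they are cut before feature extraction.
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim amounts must be non-negative")
    n_head = int(round(head_s * rec.fs))
    n_tail = int(round(tail_s * rec.fs))
    if n_head + n_tail >= rec.n_samples:
        raise ValueError(
            f"cannot trim {head_s}+{tail_s} s from a {rec.duration:.2f} s record"
        )
    stop = rec.n_samples - n_tail
    return dataclasses.replace(
        rec,
        t=np.arange(stop - n_head) / rec.fs,
        a=rec.a[n_head:stop].copy(),
    )


def magnitude(rec: AccelRecording) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(ax² + ay² + az²)."""
    return np.sqrt(np.sum(rec.a**2, axis=1))


def channel(rec: AccelRecording, mode: str = "magnitude") -> np.ndarray:
    """Reduce the 3-axis trace to the single series the analysis consumes.

    ``magnitude`` (default) is orientation-robust for a phone strapped to a
    limb; ``x``/``y``/``z`` select one axis.
    """
    if mode == "magnitude":
        return magnitude(rec)
    axes = {"x": 0, "y": 1, "z": 2}
    if mode not in axes:
        raise ValueError(f"channel mode must be magnitude/x/y/z, got {mode!r}")
    return rec.a[:, axes[mode]].copy()
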