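"""Segmentation and feature extraction.

A left and a right single-channel series are cut into M consecutive
subwindows of N samples each and stacked as the columns of a signal matrix
D (N×Q, Q = 2M; left columns first, then right, in temporal order).  Each
column is characterized in the time domain by its mean and sample standard
deviation and in the frequency domain by relative band power: the fraction
of the column's mean-removed DFT energy over bins 1..⌊N/2⌋ that falls in a
frequency band.  Selected features form the pattern matrix P (R×Q) with a
one-hot two-row target matrix T encoding left (class 1) vs right (class 2).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalMatrix",
    "SpectralMatrix",
    "FeatureSet",
    "DEFAULT_BANDS",
    "build_signal_matrix",
    "dft_columns",
    "band_power",
    "build_feature_set",
]

#: Default analysis bands (Hz), half-open, partitioning 0.5–10 Hz: the
#: repetition fundamental + first harmonics land in band 1, faster content
#: in band 2.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0.5, 3.0), (3.0, 10.0))


@dataclasses.dataclass
class SignalMatrix:
    """N×Q matrix of signal subwindows with segment bookkeeping.

    Columns 1..M come from the left series, M+1..2M from the right, each in
    temporal order; ``pair_index[q]`` is the repetition index shared by the
    paired columns q and M+q.
    """

    D: np.ndarray
    fs: float
    M: int

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("D must be 2-D")
        if self.D.shape[1] != 2 * self.M:
            raise ValueError(f"expected Q = 2·M = {2 * self.M} columns, got {self.D.shape[1]}")

    @property
    def N(self) -> int:
        return self.D.shape[0]

    @property
    def Q(self) -> int:
        return self.D.shape[1]

    @property
    def side_of_column(self) -> list[str]:
        return ["L"] * self.M + ["R"] * self.M

    @property
    def pair_index(self) -> list[int]:
        return list(range(1, self.M + 1)) * 2

    @property
    def column_labels(self) -> list[str]:
        return [f"{s}{k}" for s, k in zip(self.side_of_column, self.pair_index)]


@dataclasses.dataclass
class SpectralMatrix:
    """Column-wise DFT of a mean-removed SignalMatrix.

    ``G[k, q]`` is the coefficient at frequency ``freq[k] = k·fs/N``; the DC
    bin is exactly zero because each column's mean is removed first.
    """

    G: np.ndarray
    fs: float
    M: int

    @property
    def N(self) -> int:
        return self.G.shape[0]

    @property
    def Q(self) -> int:
        return self.G.shape[1]

    @property
    def freq(self) -> np.ndarray:
        return np.arange(self.N) * self.fs / self.N

    @property
    def resolution(self) -> float:
        """Frequency-bin spacing fs/N in Hz."""
        return self.fs / self.N


def build_signal_matrix(
    left: np.ndarray,
    right: np.ndarray,
    M: int | None = None,
    N: int | None = None,
    fs: float = 100.0,
) -> SignalMatrix:
    """Segment paired series into the N×2M signal matrix.

    Exactly one of ``M`` (segments per side) or ``N`` (samples per segment)
    is supplied; the other is derived by floor division and the trailing
    remainder is discarded.  A left/right length mismatch larger than one
    segment triggers a warning; the shorter length is used for both sides.
    """
    if (M is None) == (N is None):
        raise ValueError("supply exactly one of M or N")
    left = np.asarray(left, dtype=float).ravel()
    right = np.asarray(right, dtype=float).ravel()
    n = min(len(left), len(right))
    if M is not None:
        if M < 1:
            raise ValueError("M must be >= 1")
        N = n // M
        if N < 1:
            raise ValueError(f"series of length {n} too short for M={M} segments")
    else:
        if N < 1:
            raise ValueError("N must be >= 1")
        M = n // N
        if M < 1:
            raise ValueError(f"series of length {n} shorter than one segment (N={N})")
    if abs(len(left) - len(right)) > N:
        warnings.warn(
            f"left/right length mismatch ({len(left)} vs {len(right)}) exceeds one "
            f"segment; truncating both to {n} samples"
        )
    D = np.empty((N, 2 * M))
    for k in range(M):
        D[:, k] = left[k * N : (k + 1) * N]
        D[:, M + k] = right[k * N : (k + 1) * N]
    return SignalMatrix(D=D, fs=fs, M=M)


def dft_columns(sm: SignalMatrix) -> SpectralMatrix:
    """Column-wise DFT of the mean-removed signal matrix.

    Removing each column's mean before the transform zeroes the DC bin, so
    band powers reflect dynamics rather than static offsets (gravity).
    """
    centered = sm.D - sm.D.mean(axis=0, keepdims=True)
    return SpectralMatrix(G=np.fft.fft(centered, axis=0), fs=sm.fs, M=sm.M)


def _band_bins(spec: SpectralMatrix, band: tuple[float, float]) -> np.ndarray:
    fc1, fc2 = band
    nyquist = spec.fs / 2.0
    if not (0.0 <= fc1 < fc2 <= nyquist + 1e-12):
        raise ValueError(f"band must satisfy 0 <= fc1 < fc2 <= fs/2, got {band}")
    k = np.arange(1, spec.N // 2 + 1)
    f = k * spec.fs / spec.N
    # half-open [fc1, fc2) so adjacent bands partition the spectrum; the
    # upper spectrum edge fc2 == fs/2 is closed so a full-range band keeps
    # the Nyquist bin
    mask = (f >= fc1) & ((f < fc2) | np.isclose(fc2, nyquist) & np.isclose(f, fc2))
    return k[mask]


def band_power(spec: SpectralMatrix, band: tuple[float, float]) -> np.ndarray:
    """Relative power per column in ``band = (fc1, fc2)``, values in [0, 1].

    Numerator: |G|² summed over bins whose frequency lies in [fc1, fc2);
    denominator: |G|² over all bins 1..⌊N/2⌋.  A column with zero total
    power (constant signal) gets relative power 0 with a warning.
    """
    half = np.abs(spec.G[1 : spec.N // 2 + 1, :]) ** 2
    total = half.sum(axis=0)
    bins = _band_bins(spec, band)
    num = (np.abs(spec.G[bins, :]) ** 2).sum(axis=0) if len(bins) else np.zeros(spec.Q)
    out = np.zeros(spec.Q)
    nonzero = total > 0
    if not nonzero.all():
        warnings.warn("constant column(s): relative band power defined as 0")
    out[nonzero] = num[nonzero] / total[nonzero]
    return out


def _band_name(band: tuple[float, float]) -> str:
    return f"bandpower[{band[0]:g},{band[1]:g})"


@dataclasses.dataclass
class FeatureSet:
    """Pattern matrix P (features × segments) with target matrix T.

    Row order follows ``feature_names``; columns follow the SignalMatrix
    layout [L(1)..L(M), R(1)..R(M)].  T is 2×Q one-hot with row 1 = left.
    """

    P: np.ndarray
    feature_names: list[str]
    T: np.ndarray
    bands: tuple[tuple[float, float], ...]
    M: int
    column_labels: list[str]

    @property
    def Q(self) -> int:
        return self.P.shape[1]

    @property
    def R(self) -> int:
        return self.P.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Class label per column ('L'/'R') decoded from T."""
        return np.where(self.T[0] == 1, "L", "R")

    def select(self, names: Sequence[str]) -> "FeatureSet":
        """Restrict to a feature subset (rows), preserving order of ``names``."""
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"unknown feature(s) {missing}; have {self.feature_names}")
        idx = [self.feature_names.index(n) for n in names]
        return dataclasses.replace(self, P=self.P[idx], feature_names=list(names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.feature_names, columns=self.column_labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.17g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "P": self.P.tolist(),
            "feature_names": self.feature_names,
            "T": self.T.tolist(),
            "bands": [list(b) for b in self.bands],
            "M": self.M,
            "column_labels": self.column_labels,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSet":
        d = json.loads(Path(path).read_text())
        return cls(
            P=np.asarray(d["P"], dtype=float),
            feature_names=list(d["feature_names"]),
            T=np.asarray(d["T"], dtype=float),
            bands=tuple(tuple(b) for b in d["bands"]),
            M=int(d["M"]),
            column_labels=list(d["column_labels"]),
        )


def build_feature_set(
    sm: SignalMatrix,
    spec: SpectralMatrix | None = None,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    features: Sequence[str] = ("mean", "std", "bandpower"),
) -> FeatureSet:
    """Assemble the pattern and target matrices from selected features.

    ``features`` is a subset of {"mean", "std", "bandpower"}; "bandpower"
    expands to one row per entry of ``bands``.  The standard deviation uses
    the n−1 (sample) denominator.
    """
    if not features:
        raise ValueError("empty feature selection")
    unknown = [f for f in features if f not in ("mean", "std", "bandpower")]
    if unknown:
        raise ValueError(f"unknown feature(s) {unknown}")
    if spec is None and "bandpower" in features:
        spec = dft_columns(sm)

    rows: list[np.ndarray] = []
    names: list[str] = []
    for f in features:
        if f == "mean":
            rows.append(sm.D.mean(axis=0))
            names.append("mean")
        elif f == "std":
            rows.append(sm.D.std(axis=0, ddof=1))
            names.append("std")
        else:
            for band in bands:
                rows.append(band_power(spec, tuple(band)))
                names.append(_band_name(tuple(band)))

    T = np.zeros((2, sm.Q))
    T[0, : sm.M] = 1.0
    T[1, sm.M :] = 1.0
    return FeatureSet(
        P=np.vstack(rows),
        feature_names=names,
        T=T,
        bands=tuple(tuple(b) for b in bands),
        M=sm.M,
        column_labels=sm.column_labels,
    )
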