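"""Left/right symmetry index and global symmetry criterion.

For a non-negative feature value on each side, the per-segment symmetry
index is

    c = (1/2) * |F_L - F_R| / (F_L + F_R) * 100      (percent)

so c = 0 for identical sides and c = 50 when one side's feature vanishes.
The global criterion C of one exercise recording averages c over the M
left/right segment pairs and over a chosen feature set Ψ:

    C = (1/|Ψ|) Σ_{r∈Ψ} (1/M) Σ_{q=1}^{M} c_q(r)

The inner average runs over the M pairs (column q against column M+q), the
quantity c_q is defined for.  Results aggregate into an individuals ×
exercises table with row means, column means and column sample standard
deviations — the study-level summary a clinician reads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureSet

__all__ = [
    "PSI_PRESETS",
    "symmetry_index",
    "global_criterion",
    "aggregate_table",
    "SymmetryResult",
    "SymmetryTable",
]

logger = logging.getLogger(__name__)

#: Named feature-subset presets: "frequency" uses band powers only,
#: "mixed" adds the time-domain standard deviation.
PSI_PRESETS = {
    "frequency": ("bandpower",),
    "mixed": ("std", "bandpower"),
}


def symmetry_index(F_L, F_R, signed: bool = False):
    """Per-segment symmetry index in percent (scalar or elementwise array).

    Inputs must be non-negative (the features used — standard deviation and
    relative band power — are non-negative by construction).  Both sides
    zero is treated as perfect symmetry (c = 0): a symmetric absence of
    motion.  With ``signed=True`` the sign of F_L − F_R is kept, giving a
    directional index in [−50, 50].
    """
    FL = np.asarray(F_L, dtype=float)
    FR = np.asarray(F_R, dtype=float)
    if np.any(FL < 0) or np.any(FR < 0):
        raise ValueError("symmetry_index requires non-negative feature values")
    denom = FL + FR
    diff = FL - FR if signed else np.abs(FL - FR)
    with np.errstate(invalid="ignore", divide="ignore"):
        # ratio first, then scale: keeps the ±50 bound exact in floating point
        c = np.where(denom > 0, 50.0 * (diff / np.where(denom > 0, denom, 1.0)), 0.0)
    c = np.clip(c, -50.0 if signed else 0.0, 50.0)
    if np.any(denom == 0):
        logger.debug("degenerate segment(s): both features zero, index set to 0")
    if np.ndim(F_L) == 0 and np.ndim(F_R) == 0:
        return float(c)
    return c


@dataclasses.dataclass
class SymmetryResult:
    """Per-pair, per-feature indices and the scalar global criterion.

    ``c[q, r]`` is the index of repetition pair q+1 for feature ``psi[r]``;
    ``C`` is the grand mean (feature means averaged over features).
    """

    c: np.ndarray
    C: float
    psi: list[str]
    individual_id: str = ""
    exercise_id: str = ""
    signed: bool = False

    @property
    def M(self) -> int:
        return self.c.shape[0]

    def per_feature(self) -> pd.Series:
        """Mean index per feature (the inner averages of the criterion)."""
        return pd.Series(self.c.mean(axis=0), index=self.psi, name="c_mean")

    def summary(self) -> str:
        lines = [
            f"Symmetry criterion C = {self.C:.3f} %  "
            f"(individual={self.individual_id or '-'}, exercise={self.exercise_id or '-'}, "
            f"{self.M} segment pairs)",
            "Per-feature mean index:",
        ]
        for name, value in self.per_feature().items():
            lines.append(f"  {name:<20s} {value:7.3f}")
        return "\n".join(lines)


def _resolve_psi(fs: FeatureSet, psi) -> list[str]:
    if isinstance(psi, str):
        if psi not in PSI_PRESETS:
            raise ValueError(f"unknown Ψ preset {psi!r}; have {sorted(PSI_PRESETS)}")
        kinds = PSI_PRESETS[psi]
        names = [
            n
            for n in fs.feature_names
            if (n in kinds) or ("bandpower" in kinds and n.startswith("bandpower"))
        ]
    else:
        names = list(psi)
    if not names:
        raise ValueError("empty feature subset Ψ")
    missing = [n for n in names if n not in fs.feature_names]
    if missing:
        raise ValueError(f"Ψ contains unknown feature(s) {missing}")
    return names


def global_criterion(
    fs: FeatureSet,
    psi: str | Sequence[str] = "frequency",
    *,
    signed: bool = False,
    individual_id: str = "",
    exercise_id: str = "",
) -> SymmetryResult:
    """Compute the full index matrix and global criterion for one recording pair.

    ``psi`` is a preset name ("frequency" or "mixed") or an explicit list of
    feature names present in ``fs``.  Column q is paired with column M+q.
    """
    names = _resolve_psi(fs, psi)
    if fs.Q != 2 * fs.M:
        raise ValueError(f"unpaired columns: Q={fs.Q} is not 2·M={2 * fs.M}")
    sub = fs.select(names)
    FL = sub.P[:, : fs.M]  # R×M
    FR = sub.P[:, fs.M :]
    c = symmetry_index(FL, FR, signed=signed).T  # M×R
    C = float(c.mean(axis=0).mean())
    return SymmetryResult(
        c=c,
        C=C,
        psi=names,
        individual_id=individual_id,
        exercise_id=exercise_id,
        signed=signed,
    )


@dataclasses.dataclass
class SymmetryTable:
    """Individuals × exercises table of global criterion values.

    ``table`` holds unrounded C values (NaN for missing cells); rounding to
    one decimal happens only when rendering.  Column statistics use the
    sample (n−1) standard deviation.
    """

    table: pd.DataFrame

    @property
    def row_means(self) -> pd.Series:
        return self.table.mean(axis=1)

    @property
    def col_means(self) -> pd.Series:
        return self.table.mean(axis=0)

    @property
    def col_stds(self) -> pd.Series:
        return self.table.std(axis=0, ddof=1)

    @classmethod
    def from_cells(cls, cells: pd.DataFrame) -> "SymmetryTable":
        """Build directly from an individuals × exercises DataFrame of C values."""
        return cls(table=cells.astype(float).copy())

    def render(self) -> pd.DataFrame:
        """Presentation table: 1-decimal cells plus Mean column and Mean/Std rows."""
        out = self.table.round(1)
        out["Mean"] = self.row_means.round(1)
        mean_row = self.col_means.round(1)
        std_row = self.col_stds.round(1)
        out.loc["Mean"] = mean_row
        out.loc["Std"] = std_row
        return out

    def to_csv(self, path: str | Path) -> None:
        self.render().to_csv(path)

    def json_payload(self) -> dict:
        return {
            "individuals": [str(i) for i in self.table.index],
            "exercises": [str(c) for c in self.table.columns],
            "C": [[None if np.isnan(v) else v for v in row] for row in self.table.to_numpy()],
            "row_means": self.row_means.tolist(),
            "col_means": self.col_means.tolist(),
            "col_stds": [None if np.isnan(v) else v for v in self.col_stds],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.json_payload(), indent=1))


def aggregate_table(results: Iterable[SymmetryResult]) -> SymmetryTable:
    """Arrange per-recording criteria into the individuals × exercises table.

    One result per (individual, exercise) cell; a duplicate cell is an
    error, missing cells stay NaN and are excluded from means.
    """
    cells: dict[tuple[str, str], float] = {}
    for res in results:
        key = (res.individual_id, res.exercise_id)
        if key in cells:
            raise ValueError(f"duplicate cell for individual={key[0]!r}, exercise={key[1]!r}")
        cells[key] = res.C
    if not cells:
        raise ValueError("no results to aggregate")
    individuals = sorted({k[0] for k in cells})
    exercises = sorted({k[1] for k in cells})
    table = pd.DataFrame(np.nan, index=individuals, columns=exercises)
    for (ind, ex), value in cells.items():
        table.loc[ind, ex] = value
    return SymmetryTable(table=table)
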