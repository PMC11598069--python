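"""Bundled reference tables from a 16-participant rehabilitation study.

Two small tables accompany the package: the participant roster (age,
gender, height, BMI) and the published per-individual, per-exercise global
symmetry criterion values of the same eight-exercise study design the
synthetic cohort mirrors.  They serve as ground truth for the aggregation
arithmetic (row/column means, sample standard deviations) and as a
realistic layout example; the underlying raw recordings are not bundled.
"""

from __future__ import annotations

import io as _io

import pandas as pd

__all__ = [
    "EXERCISE_CATALOGUE",
    "load_participants",
    "load_symmetry_reference",
    "participant_summary",
]

#: The eight-exercise prehabilitation catalogue the study design uses.
EXERCISE_CATALOGUE = {
    "E1": "basic spinal motion (both legs bent)",
    "E2": "spinal motion (one leg bent)",
    "E3": "lifting of one leg (other leg on the floor)",
    "E4": "foot circles (circles in the hip joint)",
    "E5": "arm flection",
    "E6": "body cross-motion (torso rotation)",
    "E7": "leg lifting (one-leg lift)",
    "E8": "squat (high squat)",
}

_PARTICIPANTS_CSV = """\
individual,age,gender,height_cm,bmi
1,75,m,187,27.7
2,45,f,152,21.6
3,21,f,173,18.0
4,21,m,184,21.6
5,47,m,178,26.5
6,24,m,185,22.8
7,21,m,176,22.3
8,69,m,185,27.5
9,22,m,182,19.0
10,47,f,163,25.6
11,34,m,192,27.1
12,47,m,176,22.6
13,22,f,175,24.5
14,8,f,135,21.6
15,22,f,175,24.5
16,46,f,152,21.6
"""

_SYMMETRY_CSV = """\
individual,E1,E2,E3,E4,E5,E6,E7,E8
1,1.5,1.7,2.1,2.4,2.3,7.7,1.0,5.7
2,1.5,3.7,4.5,2.1,1.1,0.6,2.9,3.7
3,2.0,0.8,1.9,3.2,3.5,7.3,1.6,1.6
4,3.0,0.8,1.8,1.4,0.3,3.5,3.5,3.3
5,3.1,6.2,6.7,3.8,3.8,2.9,1.6,0.6
6,4.8,3.6,5.1,5.8,3.6,7.0,1.3,3.0
7,0.5,0.7,1.5,3.9,2.5,1.3,0.8,1.9
8,3.9,3.1,3.7,0.8,3.2,3.8,4.2,7.6
9,2.9,4.8,5.9,4.7,5.9,2.5,1.5,0.9
10,2.5,5.7,0.8,5.6,0.1,4.0,2.3,0.5
11,0.1,3.9,4.7,2.3,2.9,1.2,1.6,4.4
12,1.3,2.5,1.8,1.1,2.0,0.8,4.5,3.0
13,0.7,3.5,0.8,4.0,1.3,4.7,1.8,1.6
14,4.3,0.6,1.4,7.5,3.6,4.6,7.3,3.4
15,1.0,1.0,2.0,1.0,1.3,0.4,0.8,1.3
16,1.4,1.7,4.0,3.6,0.6,1.7,1.3,5.5
"""


def load_participants() -> pd.DataFrame:
    """Participant roster: age [years], gender (m/f), height [cm], BMI [kg/m²]."""
    return pd.read_csv(_io.StringIO(_PARTICIPANTS_CSV), index_col="individual")


def load_symmetry_reference() -> pd.DataFrame:
    """Published global symmetry criterion C per individual and exercise (percent)."""
    return pd.read_csv(_io.StringIO(_SYMMETRY_CSV), index_col="individual")


def participant_summary() -> pd.DataFrame:
    """Mean and sample (n−1) standard deviation of the numeric roster columns."""
    df = load_participants()[["age", "height_cm", "bmi"]]
    return pd.DataFrame({"mean": df.mean(), "std": df.std(ddof=1)})
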