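"""Synthetic paired left/right accelerometer recordings with known asymmetry.

The generator emulates the structure of a repetition-based rehabilitation
exercise recorded by a phone strapped to each body side: a periodic waveform
(fundamental at the repetition frequency plus one harmonic at twice that
frequency with half the amplitude, enveloped per repetition so individual
repetitions appear as bursts), a slow baseline drift, and additive white
sensor noise.  Left/right asymmetry is injected by scaling the right side's
deterministic component by ``1 + asym_amp`` and its repetition frequency by
``1 + asym_freq``; with ``asym_freq = 0`` this makes RMS(R)/RMS(L) equal
``1 + asym_amp`` exactly, which the test suite relies on.

It makes no attempt at biomechanical fidelity to any specific exercise; it
provides a ground-truth asymmetry dial against which the symmetry criterion
and the classifiers can be validated.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import AccelRecording

__all__ = ["SyntheticConfig", "EXERCISE_IDS", "EXERCISE_FREQS", "generate_pair", "generate_cohort"]

#: Exercise labels mirroring an eight-exercise catalogue.
EXERCISE_IDS = tuple(f"E{i}" for i in range(1, 9))

#: Nominal repetition frequency per exercise (Hz), spread across the
#: 0.3–2 Hz band typical of slow repetition-based exercises.
EXERCISE_FREQS = dict(zip(EXERCISE_IDS, (0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75)))

#: Relative per-axis amplitude weights (x dominant, phone on a limb).
AXIS_WEIGHTS = np.array([1.0, 0.6, 0.3])
#: Per-axis carrier phase offsets (rad).
AXIS_PHASES = np.array([0.0, np.pi / 3, 2 * np.pi / 3])
#: Baseline drift frequency (Hz): slow postural wander.
DRIFT_FREQ = 0.05


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic recording pair.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz (default 100, the usual phone rate).
    n_reps : int
        Repetitions per record (default 10).
    rep_freq : float
        Dominant motion frequency in Hz; one repetition per period.
    amp : float
        Base acceleration amplitude in m/s² (scaled per axis by AXIS_WEIGHTS).
    asym_amp : float
        Fractional right/left amplitude difference δ_a ≥ 0.
    asym_freq : float
        Fractional right/left frequency shift δ_f ≥ 0.
    noise_sd : float
        Additive white-noise standard deviation (m/s², per sample per axis).
    drift : float
        Amplitude of a 0.05 Hz baseline-drift sinusoid (m/s²).
    seed : int
        RNG seed; identical seed + config gives a bit-identical pair.
    duration_s : float or None
        Record length in seconds; None means ``n_reps / rep_freq``.
    """

    fs: float = 100.0
    n_reps: int = 10
    rep_freq: float = 0.5
    amp: float = 1.0
    asym_amp: float = 0.0
    asym_freq: float = 0.0
    noise_sd: float = 0.05
    drift: float = 0.1
    seed: int = 0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        checks = [
            ("fs", self.fs > 0),
            ("n_reps", int(self.n_reps) == self.n_reps and self.n_reps >= 1),
            ("rep_freq", self.rep_freq > 0),
            ("amp", self.amp > 0),
            ("asym_amp", self.asym_amp >= 0),
            ("asym_freq", self.asym_freq >= 0),
            ("noise_sd", self.noise_sd >= 0),
            ("drift", self.drift >= 0),
            ("duration_s", self.duration_s is None or self.duration_s > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(
                    f"invalid SyntheticConfig field {name!r} = {getattr(self, name)!r}"
                )

    @property
    def effective_duration(self) -> float:
        if self.duration_s is not None:
            return float(self.duration_s)
        return self.n_reps / self.rep_freq


def _waveform(t: np.ndarray, f: float, amp: float, drift: float) -> np.ndarray:
    """Deterministic (n, 3) template: enveloped two-tone carrier plus drift.

    The sin²(π f t) envelope is zero at every repetition boundary, so each
    repetition appears as a distinct smooth burst while keeping the signal
    exactly periodic at the repetition frequency.
    """
    envelope = np.sin(np.pi * f * t) ** 2
    drift_term = drift * np.sin(2 * np.pi * DRIFT_FREQ * t)
    out = np.empty((len(t), 3))
    for j in range(3):
        carrier = np.sin(2 * np.pi * f * t + AXIS_PHASES[j]) + 0.5 * np.sin(
            2 * np.pi * 2 * f * t + 2 * AXIS_PHASES[j]
        )
        out[:, j] = amp * AXIS_WEIGHTS[j] * envelope * carrier + drift_term
    return out


def generate_pair(config: SyntheticConfig) -> tuple[AccelRecording, AccelRecording]:
    """Generate one left/right recording pair.

    The right side's deterministic component (waveform *and* drift) is the
    left side's scaled by ``1 + asym_amp``, with the repetition frequency
    scaled by ``1 + asym_freq``; noise realizations are independent per side.
    """
    n = int(round(config.effective_duration * config.fs))
    t = np.arange(n) / config.fs
    left_det = _waveform(t, config.rep_freq, config.amp, config.drift)
    right_det = (1.0 + config.asym_amp) * _waveform(
        t, config.rep_freq * (1.0 + config.asym_freq), config.amp, config.drift
    )
    rng = np.random.default_rng(config.seed)
    left = left_det + rng.normal(0.0, config.noise_sd, size=(n, 3))
    right = right_det + rng.normal(0.0, config.noise_sd, size=(n, 3))
    common = dict(t=t, fs=config.fs)
    return (
        AccelRecording(a=left, side="L", **common),
        AccelRecording(a=right, side="R", **common),
    )


def generate_cohort(
    n_individuals: int,
    per_individual_asymmetry: list[tuple[float, float]],
    config: SyntheticConfig,
    exercises: tuple[str, ...] = EXERCISE_IDS,
) -> list[tuple[AccelRecording, AccelRecording]]:
    """Generate a labeled cohort: every individual performs every exercise.

    ``per_individual_asymmetry`` holds one ``(asym_amp, asym_freq)`` pair per
    individual.  Each (individual, exercise) cell gets its own RNG seed
    derived deterministically from ``config.seed``, so the same master seed
    reproduces the whole cohort sample-for-sample.  Exercises differ only in
    their nominal repetition frequency (EXERCISE_FREQS where known).
    """
    if len(per_individual_asymmetry) != n_individuals:
        raise ValueError(
            f"per_individual_asymmetry has {len(per_individual_asymmetry)} entries "
            f"for n_individuals={n_individuals}"
        )
    pairs: list[tuple[AccelRecording, AccelRecording]] = []
    for i, (da, df) in enumerate(per_individual_asymmetry):
        individual_id = f"S{i + 1:02d}"
        for j, ex in enumerate(exercises):
            child = np.random.SeedSequence(entropy=config.seed, spawn_key=(i, j))
            seed = int(child.generate_state(1)[0] % 2**31)
            cell_cfg = dataclasses.replace(
                config,
                seed=seed,
                asym_amp=da,
                asym_freq=df,
                rep_freq=EXERCISE_FREQS.get(ex, config.rep_freq),
            )
            left, right = generate_pair(cell_cfg)
            for rec in (left, right):
                rec.individual_id = individual_id
                rec.exercise_id = ex
            pairs.append((left, right))
    return pairs
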