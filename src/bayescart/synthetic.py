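"""Synthetic stand-ins for the neonatal sleep-EEG corpus.

Two generators are provided.  ``generate_epoch`` produces raw two-channel
signals whose spectral content is known analytically (a sinusoid at each
requested band's centre frequency plus white noise), so the feature
extractor can be checked against closed-form expectations.
``generate_table`` produces labelled 72-feature tables with the class
structure the classifier assumes: six postconceptional-age groups of ~100
recordings each, where a controllable subset of features carries
class-dependent means that increase monotonically with the age class
(mimicking maturation trends) and the remaining features are
class-independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral import BANDS, EpochSignal

#: Centre frequency (Hz) of each band; the sinusoid carrier used per band.
BAND_CENTRES: dict[str, float] = {b.name: (b.lo_hz + b.hi_hz) / 2 for b in BANDS}


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one synthetic two-channel epoch.

    band_amplitudes maps band names (``subdelta`` ... ``beta2``) to sinusoid
    amplitudes in microvolt-like units; unnamed bands default to 0.
    """

    band_amplitudes: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    duration_s: float = 10.0
    fs: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 2 * BANDS[-1].hi_hz:
            raise ValueError(
                f"fs={self.fs} Hz must exceed twice the top band edge "
                f"({BANDS[-1].hi_hz} Hz)"
            )
        unknown = set(self.band_amplitudes) - set(BAND_CENTRES)
        if unknown:
            raise ValueError(f"unknown band name(s): {sorted(unknown)}")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_epoch(spec: SignalSpec) -> EpochSignal:
    """Deterministic (given seed) two-channel epoch from a SignalSpec.

    Both channels carry the same band-centre sinusoids; the white noise is
    drawn independently per channel.
    """
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    base = np.zeros(n)
    for name, amp in spec.band_amplitudes.items():
        if amp > 0:
            base += amp * np.sin(2 * np.pi * BAND_CENTRES[name] * t)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(2, n)) if spec.noise_sd > 0 else 0.0
    return EpochSignal(np.broadcast_to(base, (2, n)).copy() + noise, spec.fs)


@dataclass(frozen=True)
class TableSpec:
    """Recipe for a labelled synthetic feature table.

    informative_idx uses 1-based feature indices, matching the CSV column
    names ``f1..fm``.  Informative features get class means spaced
    ``effect_size * noise_sd`` apart, increasing with the class index;
    all other features are i.i.d. N(0, noise_sd**2) regardless of class.
    """

    n_classes: int = 6
    n_per_class: int = 100
    n_features: int = 72
    informative_idx: tuple[int, ...] = tuple(range(1, 11))
    effect_size: float = 1.5
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 1 or self.n_features < 1:
            raise ValueError("n_per_class and n_features must be positive")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        idx = tuple(int(i) for i in self.informative_idx)
        if any(i < 1 or i > self.n_features for i in idx):
            raise ValueError(
                f"informative_idx must lie in 1..{self.n_features}, got {idx}"
            )
        if len(set(idx)) != len(idx):
            raise ValueError("informative_idx contains duplicates")
        object.__setattr__(self, "informative_idx", idx)


def generate_table(spec: TableSpec) -> pd.DataFrame:
    """Labelled feature table with columns ``f1..fm`` and integer ``label``.

    Rows are ordered by class (labels 1..C, n_per_class each); deterministic
    given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_classes * spec.n_per_class
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    labels = np.repeat(np.arange(1, spec.n_classes + 1), spec.n_per_class)
    shift = (labels - 1)[:, None] * spec.effect_size * spec.noise_sd
    cols = np.asarray(spec.informative_idx, dtype=int) - 1
    if cols.size:
        X[:, cols] += shift
    df = pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(spec.n_features)])
    df["label"] = labels.astype(int)
    return df


def split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, y); the label column is ``label``."""
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    y = table["label"].to_numpy()
    X = table.drop(columns="label").to_numpy(dtype=np.float64)
    return X, y


def week_classes(weeks: Sequence[float]) -> np.ndarray:
    """Ordinal class labels from postconceptional ages.

    Records are grouped by completed week; classes are numbered 1..K in
    increasing age order, so a cohort spanning 40-45 completed weeks yields
    six classes.
    """
    w = np.floor(np.asarray(weeks, dtype=float)).astype(int)
    if w.size == 0:
        raise ValueError("no ages given")
    uniq = np.unique(w)
    return np.searchsorted(uniq, w) + 1
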