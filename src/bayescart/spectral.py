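"""Spectral band-power features for two-channel sleep EEG.

A recording made via the central-temporal derivations C3-T3 and C4-T4 is
transformed, epoch by epoch, into the six standard neonatal frequency bands
(Subdelta through Beta2, covering 0-25 Hz).  Each location (either channel,
or their sample-wise sum) contributes an absolute and a relative power per
band, and each of those quantities also contributes a variance -- across
sub-windows of one epoch, or across epochs of one recording -- for a total
of 6 bands x {absolute, relative} x {C3-T3, C4-T4, sum} x {power, variance}
= 72 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np


class Band(NamedTuple):
    name: str
    lo_hz: float
    hi_hz: float


#: The six standard bands.  Half-open convention [lo, hi): a component at
#: exactly 3.5 Hz belongs to Theta, not Delta.  The last band closes at 25 Hz.
BANDS: tuple[Band, ...] = (
    Band("subdelta", 0.0, 1.5),
    Band("delta", 1.5, 3.5),
    Band("theta", 3.5, 7.5),
    Band("alpha", 7.5, 13.5),
    Band("beta1", 13.5, 19.5),
    Band("beta2", 19.5, 25.0),
)

#: Highest band edge; the sampling rate must resolve it.
MAX_BAND_HZ = 25.0

_KINDS = ("abs", "rel")
_LOCATIONS = ("c3t3", "c4t4", "sum")


@dataclass(frozen=True)
class EpochSignal:
    """One fixed-length two-channel EEG segment.

    Parameters
    ----------
    channels : ndarray of shape (2, n_samples)
        Sample sequences for C3-T3 and C4-T4, in microvolt-like units.
    fs : float
        Sampling rate in Hz; must cover the 25 Hz upper band edge
        (``fs >= 50``).
    """

    channels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 2 or ch.shape[0] != 2:
            raise ValueError(
                f"expected two channels of equal length, got shape {ch.shape}"
            )
        if self.fs < 2 * MAX_BAND_HZ:
            raise ValueError(
                f"fs={self.fs} Hz cannot resolve the {MAX_BAND_HZ} Hz band edge"
            )
        object.__setattr__(self, "channels", ch)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def feature_names() -> list[str]:
    """The canonical 72-slot feature layout.

    36 power features (``abs``/``rel`` x location x band, means), followed by
    the 36 matching variance features (``var_`` prefix), in the same order.
    """
    base = [
        f"{kind}_{loc}_{band.name}"
        for kind in _KINDS
        for loc in _LOCATIONS
        for band in BANDS
    ]
    return base + [f"var_{name}" for name in base]


def band_powers(
    signal: np.ndarray, fs: float, bands: Sequence[Band] = BANDS
) -> np.ndarray:
    """Absolute band powers of one channel via a single rectangular-window FFT.

    The one-sided periodogram mass ``|X(f)|^2 / N`` (doubled off DC/Nyquist)
    is summed per band with the half-open ``[lo, hi)`` convention; the last
    band includes its upper edge.  Because the bands tile 0-25 Hz, the six
    powers sum exactly to the total signal power restricted to that range
    (Parseval).

    Parameters
    ----------
    signal : 1-d array
    fs : float
        Sampling rate, Hz; must be at least 50.
    bands : sequence of Band

    Returns
    -------
    ndarray of shape (len(bands),), non-negative.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be one-dimensional with at least 2 samples")
    if fs < 2 * MAX_BAND_HZ:
        raise ValueError(f"fs={fs} Hz below the Nyquist requirement for 25 Hz bands")
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    # one-sided: double everything except DC and (for even n) the Nyquist bin
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out = np.empty(len(bands))
    last = len(bands) - 1
    for i, b in enumerate(bands):
        if i == last:
            sel = (freqs >= b.lo_hz) & (freqs <= b.hi_hz)
        else:
            sel = (freqs >= b.lo_hz) & (freqs < b.hi_hz)
        out[i] = spec[sel].sum()
    return out


def _location_signals(epoch: EpochSignal) -> list[np.ndarray]:
    c3, c4 = epoch.channels
    return [c3, c4, c3 + c4]


def _abs_rel_block(signals: list[np.ndarray], fs: float) -> np.ndarray:
    """36 quantities for one analysis window: abs then rel, per location/band."""
    abs_block = np.concatenate([band_powers(s, fs) for s in signals])
    rel = np.empty_like(abs_block)
    for i in range(len(signals)):
        seg = abs_block[6 * i : 6 * (i + 1)]
        tot = seg.sum()
        rel[6 * i : 6 * (i + 1)] = seg / tot if tot > 0 else 0.0
    return np.concatenate([abs_block, rel])


def epoch_features(epoch: EpochSignal, n_subwindows: int = 10) -> np.ndarray:
    """72-dimensional feature vector of a single epoch.

    The epoch is cut into ``n_subwindows`` contiguous equal sub-windows
    (default ten one-second windows of a 10 s epoch).  Power features are the
    means of the per-sub-window absolute and relative band powers; variance
    features are the population variances of the same quantities across
    sub-windows.
    """
    if not isinstance(epoch, EpochSignal):
        epoch = EpochSignal(np.asarray(epoch), 100.0)
    if n_subwindows < 2:
        raise ValueError("need at least 2 sub-windows to define variances")
    if epoch.n_samples < 2 * n_subwindows:
        raise ValueError("epoch too short for the requested sub-windows")
    bounds = np.linspace(0, epoch.n_samples, n_subwindows + 1).astype(int)
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sigs = [s[a:b] for s in _location_signals(epoch)]
        rows.append(_abs_rel_block(sigs, epoch.fs))
    q = np.asarray(rows)  # (n_subwindows, 36)
    return np.concatenate([q.mean(axis=0), q.var(axis=0)])


def recording_features(epochs: Sequence[EpochSignal]) -> np.ndarray:
    """72-dimensional feature vector of a whole recording.

    Each epoch contributes one 36-vector of absolute and relative band powers
    (single full-epoch FFT window); power features are the means across
    epochs and variance features the population variances across epochs.
    """
    epochs = list(epochs)
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs (variance undefined otherwise)")
    q = np.asarray(
        [_abs_rel_block(_location_signals(e), e.fs) for e in epochs]
    )
    return np.concatenate([q.mean(axis=0), q.var(axis=0)])
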