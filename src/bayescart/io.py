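"""Reading and writing the package's plain-text formats.

Feature tables are CSV with header ``f1..fm,label``; raw epochs are CSV
with one column per channel.  EDF polysomnograph files are read through
mne when it is installed (``pip install bayescart[edf]``), selecting the
two central-temporal channels by label match.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import EpochSignal

DEFAULT_CHANNEL_PATTERNS = ("C3-T3", "C4-T4")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: feature table must have a 'label' column")
    return df


def write_epoch_csv(epoch: EpochSignal, path: str | Path) -> None:
    pd.DataFrame(epoch.channels.T, columns=["c3t3", "c4t4"]).to_csv(
        path, index=False
    )


def read_epoch_csv(path: str | Path, fs: float = 100.0) -> EpochSignal:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two channel columns")
    return EpochSignal(df.to_numpy(dtype=np.float64).T, fs)


def read_edf(path: str | Path,
             channel_patterns: Sequence[str] = DEFAULT_CHANNEL_PATTERNS,
             ) -> EpochSignal:
    """Two-channel signal from an EDF recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF reading requires mne; install with `pip install bayescart[edf]`"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = []
    for pat in channel_patterns:
        match = [ch for ch in raw.ch_names if pat.lower() in ch.lower()]
        if not match:
            raise ValueError(f"{path}: no channel matching {pat!r} "
                             f"(available: {raw.ch_names})")
        picks.append(match[0])
    data = raw.get_data(picks=picks)
    return EpochSignal(np.asarray(data, dtype=np.float64),
                       float(raw.info["sfreq"]))


def iter_epochs(signal: EpochSignal, epoch_s: float = 10.0):
    """Cut a long two-channel recording into fixed-length epochs."""
    n = int(round(epoch_s * signal.fs))
    total = signal.channels.shape[1]
    for start in range(0, total - n + 1, n):
        yield EpochSignal(signal.channels[:, start:start + n], signal.fs)
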