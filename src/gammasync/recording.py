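"""Container for multichannel extracellular LFP recordings.

A recording is a channels x samples voltage matrix (microvolts) with a
sampling rate, per-channel anatomical metadata (shank id, hemisphere,
relative depth) and optional excluded epochs (e.g. sharp-wave intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns required in channel metadata.
CHANNEL_META_COLUMNS = ("shank", "side", "depth_um")


@dataclass
class LfpRecording:
    """Multichannel LFP recording.

    Parameters
    ----------
    voltages : ndarray, shape (n_channels, n_samples)
        Extracellular voltage in microvolts.
    rate : float
        Sampling rate in Hz; must be positive.
    channel_meta : DataFrame
        One row per channel with columns ``shank`` (int), ``side``
        ('L'/'R') and ``depth_um`` (float, relative depth along the shank).
    epoch_masks : list of (start_s, end_s)
        Intervals excluded from analysis. Must lie inside the recording.
    """

    voltages: np.ndarray
    rate: float
    channel_meta: pd.DataFrame
    epoch_masks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be a 2-D channels x samples array")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_meta) != self.voltages.shape[0]:
            raise ValueError(
                f"channel_meta has {len(self.channel_meta)} rows for "
                f"{self.voltages.shape[0]} channels"
            )
        missing = [c for c in CHANNEL_META_COLUMNS if c not in self.channel_meta.columns]
        if missing:
            raise ValueError(f"channel_meta missing columns: {missing}")
        dur = self.duration
        for lo, hi in self.epoch_masks:
            if not (0.0 <= lo < hi <= dur + 1e-9):
                raise ValueError(f"mask ({lo}, {hi}) outside recording of {dur} s")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.voltages.shape[1] / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.rate

    def unmasked_indices(self) -> np.ndarray:
        """Sample indices not covered by any epoch mask."""
        keep = np.ones(self.n_samples, dtype=bool)
        for lo, hi in self.epoch_masks:
            i0 = int(np.floor(lo * self.rate))
            i1 = int(np.ceil(hi * self.rate))
            keep[max(i0, 0) : min(i1, self.n_samples)] = False
        return np.nonzero(keep)[0]

    def channels_of(self, side: str | None = None, shank: int | None = None) -> np.ndarray:
        """Indices of channels matching a hemisphere and/or shank."""
        sel = np.ones(self.n_channels, dtype=bool)
        if side is not None:
            sel &= (self.channel_meta["side"] == side).to_numpy()
        if shank is not None:
            sel &= (self.channel_meta["shank"] == shank).to_numpy()
        return np.nonzero(sel)[0]

    def subset(self, channels: np.ndarray) -> "LfpRecording":
        """Recording restricted to the given channel indices."""
        return LfpRecording(
            voltages=self.voltages[channels],
            rate=self.rate,
            channel_meta=self.channel_meta.iloc[channels].reset_index(drop=True),
            epoch_masks=list(self.epoch_masks),
        )
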