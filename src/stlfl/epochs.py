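"""Labeled multichannel EEG epochs — the container passed between all stages.

An :class:`EpochSet` holds ``n_epochs`` stimulus-locked segments of shape
``(channels, time_samples)`` together with the bookkeeping every downstream
stage needs: the binary target label (1 = P300/target, 2 = non-target), the
stimulus code that elicited the epoch (row/column index 1-12 in the matrix
speller, group index 1-9 in RSVP), the character-trial index, and the
repetition index within that trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

TARGET_LABEL = 1
NONTARGET_LABEL = 2


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs with labels and speller bookkeeping.

    Parameters
    ----------
    data:
        Array of shape ``(n_epochs, n_channels, n_times)``.
    labels:
        Integer array, 1 for target (P300) epochs, 2 for non-target.
    codes:
        Stimulus code per epoch (1-12 for row/column, 1-9 for RSVP groups).
    char_index:
        Character-trial index per epoch (0-based).
    repetition_index:
        Repetition index per epoch within its character trial (0-based).
    fs:
        Sampling rate in Hz.
    channel_names:
        Optional channel labels; defaults to ``ch00 .. chNN``.
    """

    data: np.ndarray
    labels: np.ndarray
    codes: np.ndarray
    char_index: np.ndarray
    repetition_index: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_epochs, channels, times); got shape {self.data.shape}"
            )
        n = self.data.shape[0]
        if n < 1:
            raise ValueError("EpochSet needs at least one epoch")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.char_index = np.asarray(self.char_index, dtype=np.int64)
        self.repetition_index = np.asarray(self.repetition_index, dtype=np.int64)
        for name in ("labels", "codes", "char_index", "repetition_index"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},); got {arr.shape}")
        if not np.isin(self.labels, (TARGET_LABEL, NONTARGET_LABEL)).all():
            raise ValueError("labels must be 1 (target) or 2 (non-target)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        elif len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def is_target(self) -> np.ndarray:
        """Boolean mask of target epochs."""
        return self.labels == TARGET_LABEL

    def subset(self, index) -> "EpochSet":
        """Return a new EpochSet restricted to the given epoch indices/mask."""
        index = np.asarray(index)
        return replace(
            self,
            data=self.data[index],
            labels=self.labels[index],
            codes=self.codes[index],
            char_index=self.char_index[index],
            repetition_index=self.repetition_index[index],
        )

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EpochSet":
        """Return a copy with new epoch data (and optionally a new rate)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)
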