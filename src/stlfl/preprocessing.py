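"""Band-pass filtering, decimation and class balancing.

Two dataset profiles ship as presets, mirroring the standard recording
pipelines this package targets:

``hybrid_rsvp``
    0.5-25 Hz linear-phase FIR, 1 s epochs, decimation by 10 (512 Hz data).
``bci_comp``
    0.1-30 Hz third-order Butterworth, 667 ms epochs, decimation to 40 Hz
    (factor 6 on 240 Hz data).

Filtering is zero-phase (forward-backward) so P300 latency is preserved.
Decimation applies a polyphase anti-aliasing FIR before keeping every
``factor``-th sample; the output length is ``floor(T / factor)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal

from .epochs import EpochSet
from .synthetic import SpellerSession


@dataclass(frozen=True)
class DatasetProfile:
    name: str
    band: tuple[float, float]
    filter_kind: str  # "butterworth" | "fir"
    filter_order: int | None  # None -> FIR order rule 3 * fs / low_edge
    epoch_window: float  # seconds
    decimation_factor: int

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.filter_kind not in ("butterworth", "fir"):
            raise ValueError(f"unknown filter kind {self.filter_kind!r}")
        if self.decimation_factor < 1:
            raise ValueError("decimation_factor must be >= 1")


PROFILES: dict[str, DatasetProfile] = {
    "hybrid_rsvp": DatasetProfile(
        name="hybrid_rsvp", band=(0.5, 25.0), filter_kind="fir",
        filter_order=None, epoch_window=1.0, decimation_factor=10,
    ),
    "bci_comp": DatasetProfile(
        name="bci_comp", band=(0.1, 30.0), filter_kind="butterworth",
        filter_order=3, epoch_window=0.667, decimation_factor=6,
    ),
}


def _fir_order(profile: DatasetProfile, fs: float) -> int:
    if profile.filter_order is not None:
        return profile.filter_order
    order = int(round(3 * fs / profile.band[0]))
    return order + order % 2  # even order -> odd tap count, type-I linear phase


def _apply_zero_phase(x: np.ndarray, profile: DatasetProfile, fs: float) -> np.ndarray:
    low, high = profile.band
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
    if profile.filter_kind == "butterworth":
        sos = sp_signal.butter(profile.filter_order, (low, high),
                               btype="bandpass", fs=fs, output="sos")
        return sp_signal.sosfiltfilt(sos, x, axis=-1)
    taps = sp_signal.firwin(_fir_order(profile, fs) + 1, (low, high),
                            pass_zero=False, fs=fs)
    padlen = min(3 * len(taps), x.shape[-1] - 1)
    return sp_signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def bandpass(obj, profile: DatasetProfile, fs: float | None = None):
    """Zero-phase band-pass; accepts an EpochSet, SpellerSession or array.

    Arrays need an explicit ``fs``; the time axis is the last axis.  Returns
    the same type as the input with the shape unchanged.
    """
    if isinstance(obj, EpochSet):
        return obj.with_data(_apply_zero_phase(obj.data, profile, obj.fs))
    if isinstance(obj, SpellerSession):
        filtered = _apply_zero_phase(obj.continuous_signal, profile, obj.fs)
        return replace(obj, continuous_signal=filtered)
    if fs is None:
        raise ValueError("fs is required when filtering a bare array")
    return _apply_zero_phase(np.asarray(obj, dtype=np.float64), profile, fs)


def decimate(epochs: EpochSet, factor: int) -> EpochSet:
    """Anti-alias filter then downsample each epoch by ``factor``.

    New length is ``floor(T / factor)`` (the trailing remainder is trimmed
    before the polyphase FIR decimator) and ``fs`` becomes ``fs / factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return epochs.with_data(epochs.data.copy())
    t = epochs.n_times
    if factor > t:
        raise ValueError(f"factor {factor} exceeds epoch length {t}")
    t_out = t // factor
    trimmed = epochs.data[..., : t_out * factor]
    out = sp_signal.decimate(trimmed, factor, ftype="fir", axis=-1, zero_phase=True)
    return epochs.with_data(out, fs=epochs.fs / factor)


def apply_profile(epochs: EpochSet, profile: DatasetProfile) -> EpochSet:
    """Band-pass then decimate an EpochSet per the profile."""
    return decimate(bandpass(epochs, profile), profile.decimation_factor)


def balance_classes(epochs: EpochSet, seed: int) -> EpochSet:
    """Equalize class counts by replicating minority-class epochs.

    Whole copies of the minority class are appended first; the remainder is
    drawn without replacement with the given seed.  All original epochs are
    retained, so the multiset of distinct underlying epochs is unchanged.
    """
    tgt = np.flatnonzero(epochs.is_target)
    non = np.flatnonzero(~epochs.is_target)
    if len(tgt) == 0 or len(non) == 0:
        raise ValueError("both classes must be present to balance")
    minority, majority = (tgt, non) if len(tgt) < len(non) else (non, tgt)
    deficit = len(majority) - len(minority)
    if deficit == 0:
        return epochs.subset(np.arange(epochs.n_epochs))
    rng = np.random.default_rng(seed)
    extra = np.tile(minority, deficit // len(minority))
    rem = deficit % len(minority)
    if rem:
        extra = np.concatenate([extra, rng.choice(minority, size=rem, replace=False)])
    idx = np.concatenate([np.arange(epochs.n_epochs), extra])
    return epochs.subset(idx)
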