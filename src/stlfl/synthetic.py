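"""Synthetic oddball speller sessions for the two standard P300 paradigms.

The simulator produces continuous multichannel "EEG" for a row-column matrix
speller (RCP: a 6x6 alphanumeric grid whose 6 rows and 6 columns flash in
random order, 12 flashes per repetition) or an RSVP speller (9 symbol groups
shown sequentially, 9 flashes per repetition).  Flashes of the attended
character's row/column (or group) are targets and receive an added
event-related potential: a Gaussian bump in time, peaking ~300 ms
post-stimulus, loaded onto a fixed subset of channels.  The background is
per-channel AR(1) noise mixed through a random orthogonal matrix so that it
is spatially colored.

Everything is driven by a single integer seed: schedule order, ground-truth
characters, noise innovations, spatial mixing and per-flash jitter each use
an independent child stream, so e.g. the spatial structure is identical
across an SNR sweep at fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .epochs import EpochSet, NONTARGET_LABEL, TARGET_LABEL

RCP = "RCP"
RSVP = "RSVP"

#: Row-major 6x6 matrix layout (Farwell-Donchin style): letters, digits, underscore.
RCP_ALPHABET = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ123456789_")

#: 27 symbols in 9 groups of 3 for the RSVP paradigm.
RSVP_ALPHABET = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ_")

EVENT_DTYPE = np.dtype(
    [
        ("sample", np.int64),
        ("code", np.int64),
        ("is_target", np.bool_),
        ("char_index", np.int64),
        ("repetition_index", np.int64),
    ]
)


@dataclass(frozen=True)
class ParadigmSpec:
    """Geometry and timing of one speller paradigm.

    RCP flashes each of the 6 rows (codes 1-6) and 6 columns (codes 7-12)
    exactly once per repetition, in seeded random order; RSVP flashes each
    of the 9 groups (codes 1-9) once per repetition.
    """

    kind: str
    n_repetitions: int
    flash_duration: float
    isi: float
    pause_between_chars: float
    alphabet: tuple[str, ...]
    n_rows: int = 6
    n_cols: int = 6
    n_groups: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (RCP, RSVP):
            raise ValueError(f"unknown paradigm kind {self.kind!r}")
        if not 1 <= self.n_repetitions <= 15:
            raise ValueError("n_repetitions must be in 1..15")
        if self.kind == RCP and len(self.alphabet) != self.n_rows * self.n_cols:
            raise ValueError("RCP alphabet size must equal n_rows * n_cols")
        if self.kind == RSVP and len(self.alphabet) != 3 * self.n_groups:
            raise ValueError("RSVP alphabet size must equal 3 * n_groups")

    @property
    def codes(self) -> np.ndarray:
        """All valid stimulus codes (one flash each per repetition)."""
        if self.kind == RCP:
            return np.arange(1, self.n_rows + self.n_cols + 1)
        return np.arange(1, self.n_groups + 1)

    @property
    def n_flashes_per_repetition(self) -> int:
        return len(self.codes)

    @property
    def n_flashes_per_character(self) -> int:
        return self.n_flashes_per_repetition * self.n_repetitions

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony in seconds (flash + inter-stimulus interval)."""
        return self.flash_duration + self.isi

    def target_codes(self, symbol: str) -> tuple[int, ...]:
        """Stimulus codes whose flashes are targets when `symbol` is attended."""
        i = self.alphabet.index(symbol)
        if self.kind == RCP:
            return (i // self.n_cols + 1, self.n_rows + i % self.n_cols + 1)
        return (i // 3 + 1,)

    def group_of(self, symbol: str) -> int:
        """1-based RSVP group containing `symbol`."""
        if self.kind != RSVP:
            raise ValueError("group_of is only defined for RSVP")
        return self.alphabet.index(symbol) // 3 + 1


def build_paradigm(kind: str, n_repetitions: int, seed: int) -> ParadigmSpec:
    """Construct a paradigm with standard timing.

    RCP: 100 ms flashes, 75 ms inter-stimulus interval, 2.5 s pause between
    characters.  RSVP: 230 ms stimuli with no ISI; the short inter-character
    pause makes one 5-repetition trial last ~10.5 s.
    """
    if kind == RCP:
        return ParadigmSpec(
            kind=RCP,
            n_repetitions=n_repetitions,
            flash_duration=0.100,
            isi=0.075,
            pause_between_chars=2.5,
            alphabet=RCP_ALPHABET,
            seed=seed,
        )
    if kind == RSVP:
        return ParadigmSpec(
            kind=RSVP,
            n_repetitions=n_repetitions,
            flash_duration=0.230,
            isi=0.0,
            pause_between_chars=0.15,
            alphabet=RSVP_ALPHABET,
            seed=seed,
        )
    raise ValueError(f"unknown paradigm kind {kind!r}")


@dataclass(frozen=True)
class ErpTemplate:
    """Planted ERP: Gaussian bump in time times a fixed spatial loading.

    Defaults put the peak 300 ms post-stimulus with a 60 ms SD, loaded
    uniformly on the last third of channels (a crude centro-parietal proxy).
    """

    latency: float = 0.300
    width: float = 0.060
    amplitude: float = 1.0
    channel_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.channel_weights is not None:
            w = np.asarray(self.channel_weights, dtype=np.float64)
            nrm = np.linalg.norm(w)
            if not np.isclose(nrm, 1.0, atol=1e-9):
                raise ValueError("channel_weights must have unit norm")
            object.__setattr__(self, "channel_weights", w)

    def resolve_weights(self, n_channels: int) -> np.ndarray:
        if self.channel_weights is not None:
            if len(self.channel_weights) != n_channels:
                raise ValueError("channel_weights length mismatch")
            return self.channel_weights
        w = np.zeros(n_channels)
        w[-max(1, n_channels // 3):] = 1.0
        return w / np.linalg.norm(w)

    def bump(self, t: np.ndarray, latency: float | None = None) -> np.ndarray:
        lat = self.latency if latency is None else latency
        return np.exp(-0.5 * ((t - lat) / self.width) ** 2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Session-level simulation parameters.

    Defaults follow the matrix-speller recording setup emulated here: 64
    channels sampled at 240 Hz.  ``snr_db`` is the ratio of planted ERP power
    to background-noise power within the epoch window, in dB.  Single-trial
    P300 responses are weak; the -15 dB default places single-repetition
    decoding accuracy in the range observed on real matrix-speller
    recordings (see docs/methods.md).
    """

    seed: int
    n_channels: int = 64
    fs: float = 240.0
    n_characters: int = 10
    snr_db: float = -15.0
    ar_coeff: float = 0.95
    latency_jitter_sd: float = 0.02
    amplitude_jitter_sd: float = 0.2
    snr_window: float = 0.8
    lead_in: float = 0.5
    tail_pad: float = 1.5

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        if self.n_channels < 1 or self.n_characters < 1:
            raise ValueError("n_channels and n_characters must be >= 1")


@dataclass
class SpellerSession:
    """A simulated continuous recording plus its flash-event table."""

    continuous_signal: np.ndarray  # (channels, samples)
    events: np.ndarray  # structured, EVENT_DTYPE
    paradigm: ParadigmSpec
    truth: list[str]
    fs: float
    meta: dict = field(default_factory=dict)


def _ar1_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               coeff: float) -> np.ndarray:
    innov = rng.standard_normal((n_channels, n_samples))
    if coeff == 0:
        return innov
    return sp_signal.lfilter([1.0], [1.0, -coeff], innov, axis=1)


def _random_orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def simulate_session(paradigm: ParadigmSpec, config: SyntheticConfig,
                     template: ErpTemplate | None = None) -> SpellerSession:
    """Simulate one speller session.

    The flash schedule enumerates every code once per repetition in seeded
    random order.  Target flashes (attended row+column, or attended group)
    receive the ERP template with per-flash latency and amplitude jitter;
    overlapping ERPs from short SOAs add linearly.  The template amplitude is
    scaled so that ERP power over the SNR window matches ``config.snr_db``
    relative to the realized noise power.  Identical inputs give bit-identical
    output.
    """
    template = template or ErpTemplate()
    fs = config.fs
    ss = np.random.SeedSequence(entropy=(config.seed, paradigm.seed))
    rng_sched, rng_truth, rng_noise, rng_mix, rng_jit = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    codes = paradigm.codes
    n_codes = len(codes)
    spacing = int(round(paradigm.soa * fs))
    pause = int(round(paradigm.pause_between_chars * fs))

    truth = [paradigm.alphabet[i]
             for i in rng_truth.integers(0, len(paradigm.alphabet),
                                         size=config.n_characters)]

    events = []
    cursor = int(round(config.lead_in * fs))
    for ci, symbol in enumerate(truth):
        tgt = set(paradigm.target_codes(symbol))
        for rep in range(paradigm.n_repetitions):
            order = rng_sched.permutation(codes)
            for k, code in enumerate(order):
                events.append((cursor + (rep * n_codes + k) * spacing,
                               int(code), int(code) in tgt, ci, rep))
        cursor += paradigm.n_flashes_per_character * spacing + pause
    events = np.array(events, dtype=EVENT_DTYPE)

    n_samples = cursor + int(round(config.tail_pad * fs))
    noise = _ar1_noise(rng_noise, config.n_channels, n_samples, config.ar_coeff)
    noise = _random_orthogonal(rng_mix, config.n_channels) @ noise

    # Scale the template so ERP power / noise power over the SNR window
    # matches snr_db.  Powers are means over (channels x window samples).
    w_ch = template.resolve_weights(config.n_channels)
    n_win = max(1, int(round(config.snr_window * fs)))
    t_win = np.arange(n_win) / fs
    unit_power = np.mean(np.outer(w_ch, template.bump(t_win)) ** 2)
    noise_power = np.mean(noise[:, :n_samples] ** 2)
    if np.isneginf(config.snr_db) or unit_power == 0:
        amplitude = 0.0
    else:
        amplitude = np.sqrt(10.0 ** (config.snr_db / 10.0) * noise_power / unit_power)

    sig = noise
    half_support = int(round((template.latency + 4 * template.width
                              + 4 * config.latency_jitter_sd) * fs))
    for ev in events:
        lat = template.latency
        amp = amplitude
        if amp > 0:
            lat += rng_jit.normal(0.0, config.latency_jitter_sd)
            amp *= 1.0 + rng_jit.normal(0.0, config.amplitude_jitter_sd)
        else:
            # keep the jitter stream aligned regardless of amplitude
            rng_jit.normal(0.0, 1.0, size=2)
        if not ev["is_target"] or amp == 0:
            continue
        s0 = int(ev["sample"])
        s1 = min(n_samples, s0 + half_support)
        t = np.arange(s1 - s0) / fs
        sig[:, s0:s1] += amp * np.outer(w_ch, template.bump(t, latency=lat))

    overlapping = template.latency + 3 * template.width > paradigm.soa
    meta = {
        "erp_amplitude": float(amplitude),
        "noise_power": float(noise_power),
        "overlapping_erps": bool(overlapping),
        "seed": config.seed,
    }
    return SpellerSession(continuous_signal=sig, events=events,
                          paradigm=paradigm, truth=truth, fs=fs, meta=meta)


def session_to_epochs(session: SpellerSession, window_s: float) -> EpochSet:
    """Cut one epoch per flash event, time-locked to stimulus onset.

    The window is half-open ``[onset, onset + window_s)`` with
    ``floor(window_s * fs)`` samples.  Events too close to the end of the
    recording are dropped with a warning.
    """
    n_t = int(np.floor(window_s * session.fs))
    if n_t < 1:
        raise ValueError("window_s must cover at least one sample")
    n_samples = session.continuous_signal.shape[1]
    keep = session.events["sample"] + n_t <= n_samples
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} event(s) too close to recording end",
            stacklevel=2,
        )
    ev = session.events[keep]
    if len(ev) == 0:
        raise ValueError("no events fit within the recording")
    data = np.stack([session.continuous_signal[:, s:s + n_t] for s in ev["sample"]])
    labels = np.where(ev["is_target"], TARGET_LABEL, NONTARGET_LABEL)
    return EpochSet(
        data=data,
        labels=labels,
        codes=ev["code"],
        char_index=ev["char_index"],
        repetition_index=ev["repetition_index"],
        fs=session.fs,
    )
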