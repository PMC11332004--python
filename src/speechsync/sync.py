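"""Synchrony measurement core.

Implements the measurement chain that turns a pair of audio signals — a
heard syllable stream and a participant's whispered productions — into a
single phase-locking value (PLV):

    audio -> |Hilbert| envelope -> resample to 100 Hz
          -> band-pass 3.5-5.5 Hz (zero phase) -> Hilbert phase
          -> windowed PLV (5 s windows, 2 s overlap), averaged

The PLV over a window of ``T`` samples is::

    PLV = (1/T) * | sum_t exp(i * (theta1(t) - theta2(t))) |

where ``theta1`` and ``theta2`` are the instantaneous phases of the two
band-limited envelopes.  A PLV of 1 means a perfectly stable phase
relation between heard and produced speech; values near 0 mean none.

The band 3.5-5.5 Hz brackets the syllabic rate of the stimulus
(4.3-4.7 Hz), so the phase captures syllable-level rhythm rather than
faster acoustic structure.

Also provides the broadband spectral profile of produced-speech
envelopes (normalized DFT power in 1-10 Hz) used to compare the
rhythmic stability of high and low synchronizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "EnvelopeSeries",
    "PhasePair",
    "PLVResult",
    "SpectrumResult",
    "GroupSpectrum",
    "extract_envelope",
    "resample_and_band",
    "extract_phase",
    "phase_pair",
    "compute_plv",
    "spectral_profile",
    "group_average_spectra",
]


@dataclass
class EnvelopeSeries:
    """A uniformly sampled amplitude envelope.

    ``values`` are nonnegative for a raw (rectified) envelope; after
    band-pass filtering the series is zero-mean and sign changes are
    expected.
    """

    values: np.ndarray
    sample_rate_hz: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite values")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate_hz


@dataclass
class PhasePair:
    """Paired instantaneous-phase series of heard and produced envelopes."""

    theta1: np.ndarray  # heard
    theta2: np.ndarray  # produced
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.theta2 = np.asarray(self.theta2, dtype=float)
        if self.theta1.shape != self.theta2.shape or self.theta1.ndim != 1:
            raise ValueError("theta1 and theta2 must be 1-D and equally long")
        if not (np.all(np.isfinite(self.theta1)) and np.all(np.isfinite(self.theta2))):
            raise ValueError("phases must be finite")

    @property
    def T(self) -> int:
        return len(self.theta1)


@dataclass
class PLVResult:
    """Windowed phase-locking values for one participant."""

    plv_windows: np.ndarray
    window_s: float
    overlap_s: float

    def __post_init__(self) -> None:
        self.plv_windows = np.asarray(self.plv_windows, dtype=float)

    @property
    def plv_mean(self) -> float:
        return float(np.mean(self.plv_windows))

    @property
    def n_windows(self) -> int:
        return len(self.plv_windows)


@dataclass
class SpectrumResult:
    """Normalized envelope power spectrum restricted to a frequency window."""

    freqs_hz: np.ndarray
    power: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs and power must align")


@dataclass
class GroupSpectrum:
    """Per-bin mean and standard deviation of spectra within one group."""

    freqs_hz: np.ndarray
    mean_power: np.ndarray
    sd_power: np.ndarray
    group: str
    n: int


def extract_envelope(samples: Sequence[float] | "np.ndarray", sample_rate_hz: float | None = None,
                     source_id: str = "") -> EnvelopeSeries:
    """Amplitude envelope as the modulus of the analytic (Hilbert) signal.

    Accepts either an :class:`~speechsync.audio.AudioSignal` or a raw
    sample array plus ``sample_rate_hz``.
    """
    if sample_rate_hz is None:
        sig = samples
        samples = sig.samples
        sample_rate_hz = sig.sample_rate_hz
        source_id = source_id or sig.participant_id
    x = np.asarray(samples, dtype=float)
    env = np.abs(sps.hilbert(x))
    return EnvelopeSeries(env, sample_rate_hz, source_id=source_id)


def _resample(values: np.ndarray, orig_hz: float, target_hz: float) -> np.ndarray:
    """Polyphase anti-aliased resampling with exact output length."""
    if orig_hz == target_hz:
        return values.copy()
    frac = Fraction(target_hz / orig_hz).limit_denominator(10_000)
    out = sps.resample_poly(values, frac.numerator, frac.denominator)
    n_target = int(round(len(values) / orig_hz * target_hz))
    if len(out) >= n_target:
        return out[:n_target]
    return np.pad(out, (0, n_target - len(out)))


def resample_and_band(env: EnvelopeSeries, target_hz: float = 100.0,
                      band: tuple[float, float] | None = (3.5, 5.5),
                      order: int = 2) -> EnvelopeSeries:
    """Resample an envelope and band-pass it with a zero-phase filter.

    The filter is a Butterworth band-pass of the given order applied
    forward-backward (``filtfilt``), so it introduces no group delay —
    essential here because a systematic phase shift between the heard
    and produced envelopes would bias the PLV.

    Pass ``band=None`` to resample only (used for the broadband
    spectral profile).
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    vals = _resample(env.values, env.sample_rate_hz, target_hz)
    if band is not None:
        low, high = band
        if not (0.0 < low < high < target_hz / 2.0):
            raise ValueError(
                f"band {band} must satisfy 0 < low < high < Nyquist ({target_hz / 2})"
            )
        sos = sps.butter(order, [low, high], btype="bandpass", fs=target_hz, output="sos")
        vals = sps.sosfiltfilt(sos, vals)
    return EnvelopeSeries(vals, target_hz, source_id=env.source_id)


def extract_phase(env: EnvelopeSeries) -> np.ndarray:
    """Instantaneous phase (radians) of the analytic signal of ``env``.

    Meaningful only for band-limited, roughly zero-mean input.  On a
    numerically-zero series the analytic phase is undefined and the
    returned values are arbitrary; PLVs computed from such input are
    unreliable and callers should gate on signal power first.
    """
    return np.angle(sps.hilbert(env.values))


def phase_pair(heard: EnvelopeSeries, produced: EnvelopeSeries) -> PhasePair:
    """Phases of two band-limited envelopes, truncated to common length."""
    if heard.sample_rate_hz != produced.sample_rate_hz:
        raise ValueError("envelopes must share a sampling rate")
    t1 = extract_phase(heard)
    t2 = extract_phase(produced)
    n = min(len(t1), len(t2))
    return PhasePair(t1[:n], t2[:n], heard.sample_rate_hz)


def compute_plv(pair: PhasePair, window_s: float = 5.0, overlap_s: float = 2.0) -> PLVResult:
    """Windowed phase-locking value between two phase series.

    Adjacent windows share ``overlap_s`` seconds, so the hop is
    ``window_s - overlap_s`` (3 s with the defaults).  Only complete
    windows enter the result; a trailing partial window is discarded so
    every window's mean phasor averages the same number of samples.
    """
    if not 0 <= overlap_s < window_s:
        raise ValueError("need 0 <= overlap_s < window_s")
    fs = pair.sample_rate_hz
    win_n = int(round(window_s * fs))
    hop_n = int(round((window_s - overlap_s) * fs))
    if hop_n < 1:
        raise ValueError("window/overlap leave an empty hop")
    if pair.T < win_n:
        raise ValueError(
            f"signal ({pair.T} samples) shorter than one window ({win_n} samples)"
        )
    phasor = np.exp(1j * (pair.theta1 - pair.theta2))
    plvs = [
        np.abs(np.mean(phasor[start:start + win_n]))
        for start in range(0, pair.T - win_n + 1, hop_n)
    ]
    return PLVResult(np.asarray(plvs), window_s=window_s, overlap_s=overlap_s)


def spectral_profile(env: EnvelopeSeries, fmin_hz: float = 1.0,
                     fmax_hz: float = 10.0) -> SpectrumResult:
    """Normalized DFT power of a broadband envelope in [fmin, fmax] Hz.

    The DFT is taken without windowing; power outside the frequency
    window is discarded and the remainder rescaled to sum to 1, so the
    profile describes the *shape* of the rhythm spectrum, not its
    absolute level.  Expects the unfiltered (rectified) envelope —
    after the 3.5-5.5 Hz band-pass there is nothing left outside the
    band to normalize against.
    """
    x = env.values
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / env.sample_rate_hz)
    power = np.abs(spec) ** 2
    mask = (freqs >= fmin_hz) & (freqs <= fmax_hz)
    if not np.any(mask):
        raise ValueError("no DFT bins inside the frequency window; signal too short")
    power = power[mask]
    total = power.sum()
    if total <= 0:
        raise ValueError("envelope has no power in the frequency window")
    return SpectrumResult(freqs[mask], power / total, source_id=env.source_id)


def group_average_spectra(spectra: Sequence[SpectrumResult],
                          labels: Sequence[str]) -> dict[str, GroupSpectrum]:
    """Per-bin mean and SD of normalized spectra within each group label."""
    if len(spectra) == 0:
        raise ValueError("no spectra given")
    if len(spectra) != len(labels):
        raise ValueError("spectra and labels must align")
    grid = spectra[0].freqs_hz
    for s in spectra[1:]:
        if s.freqs_hz.shape != grid.shape or not np.allclose(s.freqs_hz, grid):
            raise ValueError("spectra are not on a common frequency grid")
    out: dict[str, GroupSpectrum] = {}
    for grp in dict.fromkeys(labels):  # preserve first-seen order
        stack = np.vstack([s.power for s, l in zip(spectra, labels) if l == grp])
        out[grp] = GroupSpectrum(
            freqs_hz=grid.copy(),
            mean_power=stack.mean(axis=0),
            sd_power=stack.std(axis=0),
            group=str(grp),
            n=stack.shape[0],
        )
    return out
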