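"""Synthetic stimuli, productions and cohorts.

The real study data are audio recordings of participants whispering
"ta" against an accelerating syllable stream, and the per-participant
phase-locking values (PLVs) derived from them.  This module generates
stand-ins with the statistical structure the analysis assumes, so the
whole pipeline is testable without any recording:

* :func:`generate_stimulus_envelope` — the amplitude envelope of the
  accelerating stream: constant-rate plateaus stepping from 4.3 to
  4.7 Hz in 0.1 Hz increments, one raised-cosine burst per syllable.
* :func:`simulate_production` — a participant's burst train, either
  phase-coupled to the stimulus with von Mises phase jitter
  (concentration ``coupling_kappa``; large kappa = tight locking,
  kappa 0 = uniform jitter, no locking) or self-paced at a fixed
  intrinsic rate that ignores the stimulus.
* :func:`simulate_cohort` — per-participant PLVs drawn from a
  two-component Gaussian mixture truncated to [0, 1], with covariates
  (sex, age, education, musical training) whose group dependence is
  configurable.

Defaults mirror the studied cohorts: mixture weights 0.62/0.38 with
component means 0.48 (lows) and 0.77 (highs), SDs 0.106 and 0.045.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .sync import EnvelopeSeries

__all__ = [
    "StimulusSpec",
    "SyntheticParticipantSpec",
    "CohortSimSpec",
    "generate_stimulus_envelope",
    "simulate_production",
    "simulate_cohort",
    "detect_burst_times",
    "write_envelope_wav",
    "write_envelope_csv",
    "read_envelope_csv",
    "write_cohort_csv",
]

DEFAULT_RATES_HZ = (4.3, 4.4, 4.5, 4.6, 4.7)


@dataclass
class StimulusSpec:
    """Design of the accelerating syllable stream.

    ``plateau_s`` defaults to 12 s so the five default plateaus fill
    exactly the 1-min stimulus; ``plateau_s=10`` gives the literal
    10 s-per-step reading (50 s total) and is available as a preset.
    """

    rates_hz: tuple[float, ...] = DEFAULT_RATES_HZ
    plateau_s: float = 12.0
    sample_rate_hz: float = 100.0
    burst_width_s: float = 0.11

    def __post_init__(self) -> None:
        self.rates_hz = tuple(float(r) for r in self.rates_hz)
        if len(self.rates_hz) == 0:
            raise ValueError("rates_hz must be non-empty")
        if any(b <= a for a, b in zip(self.rates_hz, self.rates_hz[1:])):
            raise ValueError("rates_hz must be strictly increasing")
        if any(r <= 0 for r in self.rates_hz):
            raise ValueError("rates must be positive")
        if self.plateau_s <= 0:
            raise ValueError("plateau_s must be positive")
        if self.sample_rate_hz <= 0 or self.burst_width_s <= 0:
            raise ValueError("sample_rate_hz and burst_width_s must be positive")

    @property
    def total_s(self) -> float:
        return len(self.rates_hz) * self.plateau_s

    def syllable_onsets(self) -> np.ndarray:
        """Onset time of every syllable, plateau by plateau."""
        onsets = []
        t0 = 0.0
        for rate in self.rates_hz:
            n_syl = int(math.floor(self.plateau_s * rate + 1e-9))
            onsets.extend(t0 + np.arange(n_syl) / rate)
            t0 += self.plateau_s
        return np.asarray(onsets)

    def local_rate(self, t: np.ndarray) -> np.ndarray:
        """Syllabic rate of the plateau containing each time point."""
        idx = np.clip((np.asarray(t) // self.plateau_s).astype(int), 0, len(self.rates_hz) - 1)
        return np.asarray(self.rates_hz)[idx]


@dataclass
class SyntheticParticipantSpec:
    """One simulated participant's production behaviour.

    ``coupled`` mode places a burst at each stimulus syllable plus a
    von Mises phase jitter of concentration ``coupling_kappa``;
    ``self_paced`` mode produces at ``self_rate_hz`` regardless of the
    stimulus (an idealized low synchronizer).  In both modes every
    burst also receives Gaussian motor timing noise of SD
    ``motor_jitter_sd_s`` (5 ms by default — human productions are
    not metronomic, and without it simulated self-paced participants
    would be bit-identical in phase and collapse any mixture fit).
    Self-paced production additionally wanders in tempo: the
    instantaneous rate follows a mean-reverting random walk around
    ``self_rate_hz`` with stationary SD ``tempo_drift_hz`` (0.3 Hz
    by default), emulating the unstable rhythm of low synchronizers —
    a drift of 0 would make them unrealistically metronomic, with a
    production spectrum sharper than a high synchronizer's.  The
    default intrinsic rate (3.5 Hz) sits below the stimulus range:
    unsynchronized whispering tends to run slower than the
    accelerating stream, and an intrinsic rate too close to the
    stimulus lets drift excursions produce spurious partial locking.
    """

    mode: str = "coupled"
    coupling_kappa: float = 16.0
    self_rate_hz: float = 3.5
    burst_width_s: float = 0.11
    motor_jitter_sd_s: float = 0.005
    tempo_drift_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("coupled", "self_paced"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")
        if not 3.0 <= self.self_rate_hz <= 6.0:
            raise ValueError("self_rate_hz must lie in [3, 6] Hz")
        if self.burst_width_s <= 0:
            raise ValueError("burst_width_s must be positive")
        if self.motor_jitter_sd_s < 0:
            raise ValueError("motor_jitter_sd_s must be >= 0")
        if self.tempo_drift_hz < 0:
            raise ValueError("tempo_drift_hz must be >= 0")


@dataclass
class CohortSimSpec:
    """A simulated cohort of PLVs plus covariates.

    PLVs are drawn from a two-component Gaussian mixture truncated to
    [0, 1] by resampling (rejection), so no probability mass piles up
    at the bounds.  Component order follows ``means``; the component
    with the larger mean is labelled ``high``.  ``music_plv_rho`` sets
    a Gaussian-copula association between PLV and years of musical
    training.
    """

    n: int = 61
    weights: tuple[float, float] = (0.62, 0.38)
    means: tuple[float, float] = (0.48, 0.77)
    sds: tuple[float, float] = (0.106, 0.045)
    sex_probs_by_group: dict = field(default_factory=lambda: {"low": 0.14, "high": 0.56})
    music_plv_rho: float = 0.2
    perceived_change_prob: float = 0.21
    cohort: str = "english"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        w = np.asarray(self.weights, dtype=float)
        if len(w) != 2 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be two nonnegative values summing to 1")
        for m, s in zip(self.means, self.sds):
            if not (0.0 < m < 1.0) or not (0.0 < s < 1.0):
                raise ValueError("means and sds must lie in (0, 1)")
        if not -1.0 < self.music_plv_rho < 1.0:
            raise ValueError("music_plv_rho must lie in (-1, 1)")


def _render_bursts(peak_times: np.ndarray, duration_s: float, fs: float,
                   width_s: float, source_id: str) -> EnvelopeSeries:
    """Overlap-add raised-cosine bursts with peaks at the given times."""
    n = int(round(duration_s * fs))
    out = np.zeros(n)
    half = width_s / 2.0
    w_n = max(3, int(round(width_s * fs)))
    t_burst = np.arange(w_n) / fs
    burst = 0.5 * (1.0 - np.cos(2.0 * np.pi * t_burst / width_s))
    for tp in peak_times:
        start = int(round((tp - half) * fs))
        lo, hi = max(0, start), min(n, start + w_n)
        if hi > lo:
            out[lo:hi] += burst[lo - start:hi - start]
    return EnvelopeSeries(out, fs, source_id=source_id)


def generate_stimulus_envelope(spec: StimulusSpec) -> EnvelopeSeries:
    """Amplitude envelope of the accelerating syllable stream.

    Each plateau holds ``floor(plateau_s * rate)`` syllables at
    constant rate; one raised-cosine burst per syllable, no gaps
    between plateaus.  The default design (4.3-4.7 Hz, 12 s plateaus)
    yields a 60 s envelope.
    """
    onsets = spec.syllable_onsets()
    peaks = onsets + spec.burst_width_s / 2.0
    return _render_bursts(peaks, spec.total_s, spec.sample_rate_hz,
                          spec.burst_width_s, source_id="stimulus")


def detect_burst_times(env: EnvelopeSeries, min_rate_hz: float = 3.0,
                       max_rate_hz: float = 6.0) -> np.ndarray:
    """Burst peak times of a syllable-train envelope, by peak picking."""
    min_dist = max(1, int(round(env.sample_rate_hz / max_rate_hz * 0.6)))
    height = 0.3 * float(np.max(env.values)) if np.max(env.values) > 0 else None
    peaks, _ = sps.find_peaks(env.values, height=height, distance=min_dist)
    return peaks / env.sample_rate_hz


def simulate_production(stim: EnvelopeSeries, spec: SyntheticParticipantSpec,
                        stim_spec: StimulusSpec | None = None) -> EnvelopeSeries:
    """Simulate a participant's "ta" burst train against a stimulus.

    In ``coupled`` mode each stimulus burst is echoed after a phase
    jitter drawn from a von Mises distribution with concentration
    ``coupling_kappa`` (converted to a time offset through the local
    syllable rate).  In ``self_paced`` mode bursts tick at the
    participant's intrinsic rate from the start of the recording.
    Deterministic for a fixed ``seed``.

    If ``stim_spec`` is given its exact onsets and local rates are
    used; otherwise burst times are recovered from the envelope by
    peak detection.
    """
    rng = np.random.default_rng(spec.seed)
    dur = stim.duration_s
    fs = stim.sample_rate_hz
    sid = f"sim-{spec.mode}-k{spec.coupling_kappa:g}-s{spec.seed}"

    if spec.mode == "self_paced":
        # instantaneous rate follows an AR(1) (Ornstein-Uhlenbeck-like)
        # process around self_rate_hz with stationary SD tempo_drift_hz
        phi = 0.5
        step_sd = spec.tempo_drift_hz * math.sqrt(1.0 - phi ** 2)
        peaks = []
        t = spec.burst_width_s / 2.0
        dev = rng.normal(0.0, spec.tempo_drift_hz) if spec.tempo_drift_hz > 0 else 0.0
        while t < dur - spec.burst_width_s / 2.0:
            peaks.append(t)
            rate = float(np.clip(spec.self_rate_hz + dev, 3.0, 6.0))
            t += 1.0 / rate
            if spec.tempo_drift_hz > 0:
                dev = phi * dev + rng.normal(0.0, step_sd)
        peaks = np.asarray(peaks) + rng.normal(0.0, spec.motor_jitter_sd_s,
                                               size=len(peaks))
        return _render_bursts(peaks[(peaks >= 0) & (peaks <= dur)], dur, fs,
                              spec.burst_width_s, sid)

    if stim_spec is not None:
        t_peaks = stim_spec.syllable_onsets() + stim_spec.burst_width_s / 2.0
        rates = stim_spec.local_rate(t_peaks)
    else:
        t_peaks = detect_burst_times(stim)
        if len(t_peaks) < 2:
            raise ValueError("could not locate syllable bursts in the stimulus envelope")
        gaps = np.diff(t_peaks)
        local = np.r_[gaps, gaps[-1]]
        rates = 1.0 / local
    jitter_phase = rng.vonmises(0.0, spec.coupling_kappa, size=len(t_peaks))
    jittered = (t_peaks + jitter_phase / (2.0 * np.pi * rates)
                + rng.normal(0.0, spec.motor_jitter_sd_s, size=len(t_peaks)))
    keep = (jittered >= 0) & (jittered <= dur)
    return _render_bursts(jittered[keep], dur, fs, spec.burst_width_s, sid)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Rejection sampling of N(mean, sd) restricted to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(good), size - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a cohort table: PLVs from the truncated mixture + covariates.

    Returns one row per participant with columns ``participant_id,
    cohort, plv, plv_true_group, sex, age, edu_years, music_years,
    music_level, perceived_change``.  ``plv_true_group`` records the
    generating mixture component (ground truth for label-recovery
    checks), independent of any later classification.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    comp = rng.choice(2, size=n, p=np.asarray(spec.weights) / np.sum(spec.weights))
    plv = np.empty(n)
    for c in (0, 1):
        idx = np.flatnonzero(comp == c)
        if len(idx):
            plv[idx] = _truncated_normal(rng, spec.means[c], spec.sds[c], len(idx))
    high_comp = int(np.argmax(spec.means))
    group = np.where(comp == high_comp, "high", "low")

    p_male = np.array([spec.sex_probs_by_group.get(g, 0.5) for g in group])
    sex = np.where(rng.random(n) < p_male, "male", "female")

    age_mean = np.where(group == "high", 24.0, 25.0)
    age_sd = np.where(group == "high", 3.0, 7.6)
    age = np.clip(np.round(rng.normal(age_mean, age_sd)), 19, 70).astype(int)
    edu = np.round(np.clip(rng.normal(15.5, 2.3, size=n), 10, 25), 1)

    # Gaussian copula: music_years shares a latent normal with the PLV z-score
    if n > 1 and np.std(plv) > 0:
        z_plv = (plv - plv.mean()) / plv.std()
    else:
        z_plv = np.zeros(n)
    rho = spec.music_plv_rho
    latent = rho * z_plv + math.sqrt(1.0 - rho ** 2) * rng.normal(size=n)
    music_years = np.round(np.clip(np.exp(1.4 + 1.0 * latent) - 1.0, 0.0, 45.0), 1)
    level = np.where(
        music_years == 0, 0,
        np.clip(np.round(1.0 + np.log1p(music_years) + 0.5 * rng.normal(size=n)), 0, 5),
    ).astype(int)
    perceived = rng.random(n) < spec.perceived_change_prob

    return pd.DataFrame({
        "participant_id": [f"{spec.cohort[:2]}{i + 1:03d}" for i in range(n)],
        "cohort": spec.cohort,
        "plv": plv,
        "plv_true_group": group,
        "sex": sex,
        "age": age,
        "edu_years": edu,
        "music_years": music_years,
        "music_level": level,
        "perceived_change": perceived,
    })


def write_envelope_wav(env: EnvelopeSeries, path: str | Path) -> None:
    """Write an envelope as a 16-bit PCM WAV at its own sampling rate."""
    peak = float(np.max(np.abs(env.values))) or 1.0
    data = np.round(env.values / peak * 32767.0).astype(np.int16)
    wavfile.write(Path(path), int(round(env.sample_rate_hz)), data)


def write_envelope_csv(env: EnvelopeSeries, path: str | Path) -> None:
    """Write an envelope as two-column CSV (time_s, amplitude)."""
    pd.DataFrame({"time_s": env.times(), "amplitude": env.values}).to_csv(
        Path(path), index=False)


def read_envelope_csv(path: str | Path, source_id: str = "") -> EnvelopeSeries:
    """Read a two-column (time_s, amplitude) envelope CSV."""
    df = pd.read_csv(Path(path))
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, amplitude")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return EnvelopeSeries(df["amplitude"].to_numpy(dtype=float), fs,
                          source_id=source_id or Path(path).stem)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(Path(path), index=False)
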