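"""Stimulus synthesis for the ten suprathreshold assessments.

Four stimulus families:

* **Temporal gap** — two 4-ms 500-Hz tone bursts separated by a silent gap
  (the adaptive parameter), presented diotically at 80 dB SPL.
* **FM tones** — 2-Hz sinusoidal frequency modulation of a pure-tone carrier
  drawn uniformly from 460-550 Hz, 400 ms at 75 dB SPL.  The dichotic
  variant inverts the modulator at the right ear, sweeping the interaural
  phase difference; the diotic variant modulates both ears in phase.
* **Modulated noise** — broadband 0.4-8 kHz noise built in the frequency
  domain, with sinusoidal temporal (4 Hz), spectral (2 cycles/octave) or
  spectro-temporal modulation applied as a per-component gain on a
  logarithmic amplitude scale.  Depth is measured mid-to-peak in dB.
* **Notched noise** — 10 000 sinusoidal components distributed exponentially
  in frequency with a -3 dB/octave power slope, either covering 1.2-2.8 kHz
  or split into 0.8-1.6 and 2.4-3.2 kHz leaving an 800-Hz notch around the
  2-kHz, 45-dB-SPL target tone.

All synthesizers are deterministic given (spec, seed) and set their printed
dB SPL levels through the shared calibration map.  Gating ramps, which the
battery definition leaves open, are raised-cosine: full Hann envelopes on
the 4-ms gap bursts, 10-ms on/off ramps everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_core import (
    DEFAULT_SAMPLE_RATE,
    AudioBuffer,
    CalibrationMap,
    set_rms_level,
)

RAMP_MS = 10.0


def _raised_cosine_ramps(n: int, sr: int, ramp_ms: float = RAMP_MS) -> np.ndarray:
    """Envelope with raised-cosine on/off ramps (flat-topped)."""
    n_ramp = min(int(round(ramp_ms / 1000.0 * sr)), n // 2)
    env = np.ones(n)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


# ---------------------------------------------------------------------------
# Temporal gap

@dataclass(frozen=True)
class GapSpec:
    """Gap-detection stimulus: two tone bursts around a silent gap."""

    gap_ms: float = 20.0           # adaptive parameter
    burst_freq: float = 500.0      # Hz
    burst_dur_ms: float = 4.0
    level_db_spl: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_ms <= 100.0:
            raise ValueError("gap must lie in [0, 100] ms")
        if self.burst_dur_ms <= 0:
            raise ValueError("burst duration must be positive")


def synth_gap(
    spec: GapSpec,
    cal: CalibrationMap,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioBuffer:
    """Render burst-gap-burst, diotic.

    The gap is the silence between the 0%-envelope offset of burst 1 and the
    0%-envelope onset of burst 2.  The level target applies to the tone
    bursts (silence carries no energy), so burst amplitude does not vary
    with gap length.
    """
    n_burst = int(round(spec.burst_dur_ms / 1000.0 * sample_rate))
    t = np.arange(n_burst) / sample_rate
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_burst) / n_burst))  # full Hann
    burst = np.sin(2 * np.pi * spec.burst_freq * t) * env
    target_rms = cal.rms_from_spl(spec.level_db_spl)
    burst *= target_rms / np.sqrt(np.mean(burst**2))
    n_gap = int(round(spec.gap_ms / 1000.0 * sample_rate))
    mono = np.concatenate([burst, np.zeros(n_gap), burst])
    return AudioBuffer(np.column_stack([mono, mono]), sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# Frequency modulation

@dataclass(frozen=True)
class FMSpec:
    """FM-detection stimulus: sinusoidal FM of a randomized pure-tone carrier.

    ``depth_hz`` is the peak frequency deviation (the adaptive parameter);
    depth 0 renders the pure-tone standard.  ``dichotic`` inverts the
    modulator at the right ear so the interaural phase difference sweeps
    continuously at the modulation rate.
    """

    depth_hz: float                # adaptive parameter
    dichotic: bool = False
    rate_hz: float = 2.0
    carrier_range: tuple[float, float] = (460.0, 550.0)
    duration_ms: float = 400.0
    level_db_spl: float = 75.0

    def __post_init__(self) -> None:
        if self.depth_hz < 0:
            raise ValueError("FM depth must be non-negative")


def synth_fm(
    spec: FMSpec,
    rng: np.random.Generator,
    cal: CalibrationMap,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioBuffer:
    """Render an FM tone (or the pure-tone standard at depth 0).

    The carrier is freshly drawn per call from ``carrier_range`` — this is
    what defeats a simple pitch-matching strategy, since every interval's
    standard sits at a different frequency.  The modulator starting phase is
    drawn uniformly so stimulus onset carries no consistent cue.

    Instantaneous frequency: ``f(t) = carrier + depth * sin(2π rate t + φ0)``
    (right ear: depth sign-inverted when dichotic).
    """
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    carrier = rng.uniform(*spec.carrier_range)
    phi0 = rng.uniform(0, 2 * np.pi)
    env = _raised_cosine_ramps(n, sample_rate)

    def channel(depth: float) -> np.ndarray:
        if spec.rate_hz == 0 or depth == 0:
            phase = 2 * np.pi * carrier * t
        else:
            # integral of f(t): carrier*t - (depth/rate)/(2π)... in phase terms
            phase = 2 * np.pi * carrier * t + (depth / spec.rate_hz) * (
                np.cos(phi0) - np.cos(2 * np.pi * spec.rate_hz * t + phi0)
            )
        return np.sin(phase) * env

    left = channel(spec.depth_hz)
    right = channel(-spec.depth_hz) if spec.dichotic else left
    buf = AudioBuffer(np.column_stack([left, right]), sample_rate=sample_rate)
    return set_rms_level(buf, spec.level_db_spl, cal)


# ---------------------------------------------------------------------------
# Modulated broadband noise (TM / SM / STM)

@dataclass(frozen=True)
class ModNoiseSpec:
    """Broadband-noise stimulus with log-amplitude sinusoidal modulation.

    ``depth_db`` is the mid-to-peak modulation depth on the dB scale (the
    adaptive parameter, 0 = flat standard).  ``tm_rate_hz`` and
    ``sm_density_cpo`` select the family: temporal only, spectral only, or
    joint spectro-temporal ripple whose drift ``direction`` is 'up' or
    'down' in frequency.
    """

    depth_db: float                 # adaptive parameter, mid-to-peak dB
    tm_rate_hz: float = 0.0
    sm_density_cpo: float = 0.0     # cycles per octave
    direction: str = "down"         # STM drift: 'up' or 'down'
    band_hz: tuple[float, float] = (400.0, 8000.0)
    duration_ms: float = 500.0
    level_db_spl: float = 65.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth_db <= 40.0:
            raise ValueError("modulation depth must lie in [0, 40] dB")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


def synth_modulated_noise(
    spec: ModNoiseSpec,
    rng: np.random.Generator,
    cal: CalibrationMap,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioBuffer:
    """Render modulated (or flat) broadband noise, diotic.

    The carrier uses every FFT component in the 0.4-8 kHz band — the
    maximum number the sampling rate allows for the duration — with random
    (Rayleigh) amplitudes and uniform phases.  The modulation gain surface

        ``G(t, x) = depth_db * sin(2π (tm_rate*t ± sm_density*x) + φ) [dB]``

    with ``x = log2(f / f_low)`` is applied per component, making the
    mid-to-peak dB depth exact by construction.  '+' drifts the ripple
    downward in frequency over time, '-' upward.
    """
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    in_band = (freqs >= spec.band_hz[0]) & (freqs <= spec.band_hz[1])
    f_k = freqs[in_band]
    n_comp = f_k.size
    amp = rng.rayleigh(scale=1.0, size=n_comp)
    phase = rng.uniform(0, 2 * np.pi, size=n_comp)
    t = np.arange(n) / sample_rate

    if spec.depth_db == 0 or (spec.tm_rate_hz == 0 and spec.sm_density_cpo == 0):
        # Flat standard: single inverse FFT.
        spectrum = np.zeros(freqs.size, dtype=complex)
        spectrum[in_band] = amp * np.exp(1j * phase)
        mono = np.fft.irfft(spectrum, n=n)
    elif spec.sm_density_cpo == 0:
        # Pure temporal modulation: one dB gain trajectory for all
        # components, applied as a time-domain envelope on the flat carrier.
        spectrum = np.zeros(freqs.size, dtype=complex)
        spectrum[in_band] = amp * np.exp(1j * phase)
        flat = np.fft.irfft(spectrum, n=n)
        phi = rng.uniform(0, 2 * np.pi)
        gain = 10.0 ** (
            spec.depth_db * np.sin(2 * np.pi * spec.tm_rate_hz * t + phi) / 20.0
        )
        mono = flat * gain
    elif spec.tm_rate_hz == 0:
        # Pure spectral modulation: static per-component dB gain.
        x = np.log2(f_k / spec.band_hz[0])
        phi = rng.uniform(0, 2 * np.pi)
        gain = 10.0 ** (
            spec.depth_db * np.sin(2 * np.pi * spec.sm_density_cpo * x + phi) / 20.0
        )
        spectrum = np.zeros(freqs.size, dtype=complex)
        spectrum[in_band] = amp * gain * np.exp(1j * phase)
        mono = np.fft.irfft(spectrum, n=n)
    else:
        x = np.log2(f_k / spec.band_hz[0])
        phi = rng.uniform(0, 2 * np.pi)
        sign = +1.0 if spec.direction == "down" else -1.0
        # Time-varying per-component gain; chunked to bound memory.
        mono = np.zeros(n)
        theta_k = sign * 2 * np.pi * spec.sm_density_cpo * x + phi
        chunk = 4096
        for start in range(0, n, chunk):
            tt = t[start : start + chunk]
            arg = 2 * np.pi * spec.tm_rate_hz * tt[None, :] + theta_k[:, None]
            gain = 10.0 ** (spec.depth_db * np.sin(arg) / 20.0)
            carrier = amp[:, None] * np.cos(
                2 * np.pi * f_k[:, None] * tt[None, :] + phase[:, None]
            )
            mono[start : start + chunk] = np.sum(gain * carrier, axis=0)

    env = _raised_cosine_ramps(n, sample_rate)
    mono *= env / np.max(np.abs(mono))
    buf = AudioBuffer(np.column_stack([mono, mono]), sample_rate=sample_rate)
    return set_rms_level(buf, spec.level_db_spl, cal)


# ---------------------------------------------------------------------------
# Notched noise

@dataclass(frozen=True)
class NotchSpec:
    """Tone-in-noise stimulus for the notched-noise frequency-resolution test.

    The masker has 10 000 sinusoidal components distributed exponentially in
    frequency with a -3 dB/octave power slope, covering 1.2-2.8 kHz
    (no-notch) or 0.8-1.6 plus 2.4-3.2 kHz (notch), and its RMS level is the
    adaptive parameter.  The target is a 2-kHz tone at 45 dB SPL.
    """

    masker_level_db_spl: float = 35.0   # adaptive parameter
    notch: bool = False
    n_components: int = 10_000
    band_no_notch: tuple[float, float] = (1200.0, 2800.0)
    bands_notch: tuple[tuple[float, float], ...] = ((800.0, 1600.0), (2400.0, 3200.0))
    duration_ms: float = 500.0
    target_freq: float = 2000.0
    target_level_db_spl: float = 45.0

    def __post_init__(self) -> None:
        if not 25.0 <= self.masker_level_db_spl <= 90.0:
            raise ValueError("masker level must lie in [25, 90] dB SPL")


def _exponential_frequencies(
    bands: tuple[tuple[float, float], ...], n_total: int
) -> np.ndarray:
    """Log-spaced component frequencies, density matched across sub-bands."""
    widths = np.array([np.log2(hi / lo) for lo, hi in bands])
    counts = np.floor(n_total * widths / widths.sum()).astype(int)
    counts[0] += n_total - counts.sum()  # exact total
    parts = [
        np.geomspace(lo, hi, num=c, endpoint=False) for (lo, hi), c in zip(bands, counts)
    ]
    return np.concatenate(parts)


def synth_notched_noise(
    spec: NotchSpec,
    rng: np.random.Generator,
    cal: CalibrationMap,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> tuple[AudioBuffer, AudioBuffer]:
    """Render (masker, target) for one interval.

    Component amplitudes scale as ``f^-1/2`` so that with constant
    per-octave component density the per-octave power falls 3 dB/octave.
    With the notch active no component falls in 1.6-2.4 kHz.
    """
    bands = spec.bands_notch if spec.notch else (spec.band_no_notch,)
    f_k = _exponential_frequencies(bands, spec.n_components)
    amp = f_k ** -0.5
    phase = rng.uniform(0, 2 * np.pi, size=f_k.size)
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    mono = np.zeros(n)
    chunk = 2000
    for start in range(0, f_k.size, chunk):
        sl = slice(start, start + chunk)
        mono += amp[sl] @ np.cos(
            2 * np.pi * f_k[sl, None] * t[None, :] + phase[sl, None]
        )
    env = _raised_cosine_ramps(n, sample_rate)
    mono *= env / np.max(np.abs(mono))
    masker = set_rms_level(
        AudioBuffer(np.column_stack([mono, mono]), sample_rate=sample_rate),
        spec.masker_level_db_spl,
        cal,
    )
    tone = np.sin(2 * np.pi * spec.target_freq * t) * env
    target = set_rms_level(
        AudioBuffer(np.column_stack([tone, tone]), sample_rate=sample_rate),
        spec.target_level_db_spl,
        cal,
    )
    return masker, target


# ---------------------------------------------------------------------------
# Spatial release from masking (trial records; audio is schematic)

SRM_COLORS = ("red", "green", "blue", "white")
SRM_NUMBERS = (1, 2, 3, 4, 5, 6, 7, 8)
SRM_CALL_SIGN = "Charlie"


@dataclass(frozen=True)
class SRMTrialRecord:
    """One speech-on-speech trial: keywords, levels and azimuths.

    The response grid is 4 colors x 8 numbers.  Audio rendering of the
    speech corpus is out of scope; :func:`synth_srm_trial` attaches a
    schematic tone-complex placeholder so the trial can still be auditioned
    and written to WAV.
    """

    target_color: str
    target_number: int
    masker_keywords: tuple[tuple[str, int], tuple[str, int]]
    target_level_db_spl: float
    masker_level_db_spl: float
    target_azimuth_deg: float
    masker_azimuths_deg: tuple[float, float]

    def __post_init__(self) -> None:
        for az in (self.target_azimuth_deg, *self.masker_azimuths_deg):
            if az not in (0.0, -45.0, 45.0):
                raise ValueError("azimuths must be 0 or ±45 degrees")
        if self.target_color not in SRM_COLORS:
            raise ValueError(f"unknown color {self.target_color!r}")
        if self.target_number not in SRM_NUMBERS:
            raise ValueError(f"number must be 1-8, got {self.target_number}")

    @property
    def tmr_db(self) -> float:
        return self.target_level_db_spl - self.masker_level_db_spl


def synth_srm_trial(
    rng: np.random.Generator,
    cal: CalibrationMap,
    *,
    separated: bool,
    target_level_db_spl: float = 65.0,
    masker_level_db_spl: float = 55.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> tuple[SRMTrialRecord, AudioBuffer]:
    """Draw one color/number trial and a schematic placeholder buffer.

    Colocated: target and both maskers at 0°.  Separated: maskers at ±45°.
    The placeholder audio is a labelled tone complex (one component per
    talker), not speech.
    """
    colors = rng.permutation(len(SRM_COLORS))
    numbers = rng.permutation(len(SRM_NUMBERS))
    record = SRMTrialRecord(
        target_color=SRM_COLORS[colors[0]],
        target_number=SRM_NUMBERS[numbers[0]],
        masker_keywords=(
            (SRM_COLORS[colors[1]], SRM_NUMBERS[numbers[1]]),
            (SRM_COLORS[colors[2]], SRM_NUMBERS[numbers[2]]),
        ),
        target_level_db_spl=target_level_db_spl,
        masker_level_db_spl=masker_level_db_spl,
        target_azimuth_deg=0.0,
        masker_azimuths_deg=(-45.0, 45.0) if separated else (0.0, 0.0),
    )
    # Schematic audio: target talker as a 400 Hz tone, maskers at 300/500 Hz,
    # panned hard by azimuth sign.
    n = int(round(0.5 * sample_rate))
    t = np.arange(n) / sample_rate
    env = _raised_cosine_ramps(n, sample_rate)
    t_rms = cal.rms_from_spl(target_level_db_spl)
    m_rms = cal.rms_from_spl(masker_level_db_spl)
    left = np.sin(2 * np.pi * 400 * t) * t_rms * np.sqrt(2)
    right = left.copy()
    for f, az in zip((300.0, 500.0), record.masker_azimuths_deg):
        tone = np.sin(2 * np.pi * f * t) * m_rms * np.sqrt(2)
        if az <= 0:
            left += tone * (1.0 if az < 0 else 0.5)
        if az >= 0:
            right += tone * (1.0 if az > 0 else 0.5)
    stereo = np.column_stack([left * env, right * env])
    peak = np.max(np.abs(stereo))
    if peak > 1.0:
        stereo /= peak
    return record, AudioBuffer(stereo, sample_rate=sample_rate)
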