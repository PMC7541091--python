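"""Sampled-audio container, level calibration, trial assembly, and WAV I/O.

Every stimulus synthesizer in this package emits an :class:`AudioBuffer`:
stereo floating-point audio on a full-scale ±1.0 grid, tied to a dB SPL
reference through a :class:`CalibrationMap`.  Four-interval two-cue 2AFC
trials are assembled with :func:`assemble_trial`.

Clipping policy is fail-fast: a level request that would push any sample
past full scale raises instead of saturating, because silent saturation
would corrupt modulation depths downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 44100
#: dB SPL produced by a 0 dBFS-RMS signal.  Keeps all stimulus levels used by
#: the battery (45-80 dB SPL) at least 20 dB below full scale.
DEFAULT_DBFS_TO_DBSPL = 100.0


@dataclass(frozen=True)
class CalibrationMap:
    """Mapping between digital RMS level (dBFS) and acoustic level (dB SPL).

    Stands in for a measured headphone/tablet calibration chain: a signal at
    0 dBFS RMS is defined to play back at ``dbfs_to_dbspl_offset`` dB SPL.
    """

    dbfs_to_dbspl_offset: float = DEFAULT_DBFS_TO_DBSPL

    def __post_init__(self) -> None:
        if not np.isfinite(self.dbfs_to_dbspl_offset):
            raise ValueError("calibration offset must be finite")

    def spl_from_rms(self, rms: float) -> float:
        """dB SPL of a signal with the given full-scale RMS."""
        if rms <= 0:
            raise ValueError("cannot compute SPL of a silent signal")
        return self.dbfs_to_dbspl_offset + 20.0 * np.log10(rms)

    def rms_from_spl(self, level_db_spl: float) -> float:
        """Full-scale RMS that plays back at the requested dB SPL."""
        return 10.0 ** ((level_db_spl - self.dbfs_to_dbspl_offset) / 20.0)


@dataclass(frozen=True)
class AudioBuffer:
    """Stereo sampled audio, full-scale ±1.0, with an attached sample rate.

    ``samples`` has shape ``(n_frames, 2)``.  Construction validates
    finiteness and the no-clipping invariant.
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim == 1:
            arr = np.column_stack([arr, arr])
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("samples must be (n_frames, 2) or mono (n_frames,)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        peak = float(np.max(np.abs(arr))) if arr.size else 0.0
        if peak > 1.0 + 1e-12:
            raise ValueError(
                f"samples clip: peak {peak:.4f} exceeds full scale by "
                f"{20 * np.log10(peak):.2f} dB"
            )
        object.__setattr__(self, "samples", arr)

    @property
    def n_channels(self) -> int:
        return 2

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_frames / self.sample_rate

    def rms(self) -> float:
        """RMS over both channels (full-scale units)."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def level_db_spl(self, cal: CalibrationMap) -> float:
        """Calibrated level in dB SPL."""
        return cal.spl_from_rms(self.rms())


def set_rms_level(
    buffer: AudioBuffer, level_db_spl: float, cal: CalibrationMap
) -> AudioBuffer:
    """Scale a buffer so its calibrated RMS level equals ``level_db_spl``.

    Pure scaling: the waveform shape is unchanged.  Raises on silent input
    and on any request that would clip, naming the peak overshoot.
    """
    rms = buffer.rms()
    if rms <= 0:
        raise ValueError("cannot set the level of a silent buffer")
    target_rms = cal.rms_from_spl(level_db_spl)
    gain = target_rms / rms
    peak = float(np.max(np.abs(buffer.samples))) * gain
    if peak > 1.0 + 1e-12:
        raise ValueError(
            f"level {level_db_spl:.1f} dB SPL would clip: peak "
            f"{20 * np.log10(peak):.2f} dB above full scale"
        )
    return replace(buffer, samples=buffer.samples * gain)


@dataclass(frozen=True)
class TrialSequence:
    """One two-cue 2AFC trial: four intervals, target in slot 2 or 3.

    Intervals 1 and 4 are standard cues.  Inter-stimulus silence and the
    inter-trial interval are timing metadata; :meth:`render` materialises
    the ISI gaps as digital zero.
    """

    intervals: tuple[AudioBuffer, AudioBuffer, AudioBuffer, AudioBuffer]
    target_position: int  # 1-based, in {2, 3}
    isi_ms: float = 250.0
    iti_s: float = 1.0

    def __post_init__(self) -> None:
        if len(self.intervals) != 4:
            raise ValueError("a trial has exactly 4 intervals")
        if self.target_position not in (2, 3):
            raise ValueError("target_position must be 2 or 3")
        rates = {b.sample_rate for b in self.intervals}
        if len(rates) != 1:
            raise ValueError("all intervals must share a sample rate")

    @property
    def total_duration(self) -> float:
        """Stimulus-sequence duration in seconds (4 intervals + 3 ISIs)."""
        return sum(b.duration for b in self.intervals) + 3 * self.isi_ms / 1000.0

    def render(self) -> AudioBuffer:
        """Concatenate the four intervals with ISI silences."""
        sr = self.intervals[0].sample_rate
        gap = np.zeros((int(round(self.isi_ms / 1000.0 * sr)), 2))
        parts: list[np.ndarray] = []
        for i, buf in enumerate(self.intervals):
            parts.append(buf.samples)
            if i < 3:
                parts.append(gap)
        return AudioBuffer(np.concatenate(parts), sample_rate=sr)


def assemble_trial(
    standard: AudioBuffer,
    target: AudioBuffer,
    position: int,
    *,
    second_standard: AudioBuffer | None = None,
    isi_ms: float = 250.0,
    iti_s: float = 1.0,
) -> TrialSequence:
    """Build the four-interval sequence [standard, A, B, standard].

    The target occupies ``position`` (2 or 3); the other inner slot holds a
    standard.  Pass ``second_standard`` when the task requires freshly drawn
    standards per interval (e.g. the carrier-randomized FM tests); it
    defaults to reusing ``standard``.
    """
    if position not in (2, 3):
        raise ValueError("target position must be 2 or 3")
    if standard.sample_rate != target.sample_rate:
        raise ValueError("standard and target must share a sample rate")
    other = second_standard if second_standard is not None else standard
    inner = (target, other) if position == 2 else (other, target)
    return TrialSequence(
        intervals=(standard, inner[0], inner[1], standard),
        target_position=position,
        isi_ms=isi_ms,
        iti_s=iti_s,
    )


def write_wav(buffer: AudioBuffer, path, *, subtype: str = "float32") -> None:
    """Write a buffer to a RIFF/WAVE file (``float32`` or ``pcm16``)."""
    if subtype == "float32":
        wavfile.write(path, buffer.sample_rate, buffer.samples.astype(np.float32))
    elif subtype == "pcm16":
        scaled = np.clip(np.round(buffer.samples * 32767.0), -32768, 32767)
        wavfile.write(path, buffer.sample_rate, scaled.astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype!r}")


def read_wav(path) -> AudioBuffer:
    """Read a WAV file written by :func:`write_wav` back to an AudioBuffer."""
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
        data = np.clip(data, -1.0, 1.0)
    else:
        data = data.astype(np.float64)
    return AudioBuffer(data, sample_rate=int(sr))
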