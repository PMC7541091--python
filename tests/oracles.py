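"""Independent signal-analysis oracles for rendered stimuli.

These recover stimulus parameters from the waveform alone (envelope fits,
Welch spectra, analytic-signal instantaneous frequency), deliberately not
reusing any synthesis-path code.
"""

import numpy as np
from scipy.signal import hilbert, welch


def fit_sinusoid(x_axis: np.ndarray, y: np.ndarray, cycles_per_unit: float):
    """Least-squares fit of a + b*sin + c*cos; returns (offset, amplitude, phase)."""
    design = np.column_stack(
        [
            np.ones(x_axis.size),
            np.sin(2 * np.pi * cycles_per_unit * x_axis),
            np.cos(2 * np.pi * cycles_per_unit * x_axis),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[0], float(np.hypot(coef[1], coef[2])), float(np.arctan2(coef[2], coef[1]))


def tm_depth_from_waveform(x: np.ndarray, sr: int, rate_hz: float) -> float:
    """Mid-to-peak dB depth of temporal modulation via short-time RMS fit."""
    win = int(sr * 0.01)
    n = len(x) // win
    env = np.sqrt(np.mean(x[: n * win].reshape(n, win) ** 2, axis=1))
    t = (np.arange(n) + 0.5) * win / sr
    env_db = 20 * np.log10(env)
    mask = (t > 0.05) & (t < len(x) / sr - 0.05)  # exclude gating ramps
    _, amp, _ = fit_sinusoid(t[mask], env_db[mask], rate_hz)
    return amp


def sm_depth_from_waveform(
    x: np.ndarray, sr: int, density_cpo: float, f_low: float = 400.0
) -> float:
    """Mid-to-peak dB depth of spectral modulation via Welch-spectrum fit."""
    f, p = welch(x, fs=sr, nperseg=16384)
    sel = (f >= 500) & (f <= 7000)
    octaves = np.log2(f[sel] / f_low)
    _, amp, _ = fit_sinusoid(octaves, 10 * np.log10(p[sel]), density_cpo)
    return amp


def fm_depth_from_waveform(x: np.ndarray, sr: int, rate_hz: float):
    """(carrier, depth) in Hz from the analytic signal's instantaneous freq."""
    inst_f = np.diff(np.unwrap(np.angle(hilbert(x)))) * sr / (2 * np.pi)
    i0, i1 = int(0.05 * sr), len(inst_f) - int(0.05 * sr)
    t = np.arange(i0, i1) / sr
    carrier, depth, _ = fit_sinusoid(t, inst_f[i0:i1], rate_hz)
    return float(carrier), depth


def interaural_phase_difference(left: np.ndarray, right: np.ndarray, sr: int):
    """IPD trace (radians) over the steady-state portion of the stimulus."""
    ipd = np.angle(hilbert(left) * np.conj(hilbert(right)))
    i0 = int(0.05 * sr)
    return ipd[i0 : len(ipd) - i0]


def band_power_db(x: np.ndarray, sr: int, lo: float, hi: float) -> float:
    f, p = welch(x, fs=sr, nperseg=16384)
    sel = (f >= lo) & (f < hi)
    return float(10 * np.log10(np.trapezoid(p[sel], f[sel])))


def per_octave_slope(x: np.ndarray, sr: int, lo: float, hi: float) -> float:
    """Slope (dB/octave) of quarter-octave band powers across [lo, hi]."""
    n_bands = int(np.floor(np.log2(hi / lo) * 4))
    edges = lo * 2.0 ** (np.arange(n_bands + 1) / 4)
    powers = [band_power_db(x, sr, a, b) for a, b in zip(edges[:-1], edges[1:])]
    centers = np.log2(np.sqrt(edges[:-1] * edges[1:]))
    return float(np.polyfit(centers, powers, 1)[0])


def stm_ripple_drift(x: np.ndarray, sr: int, density_cpo: float, f_low: float = 400.0):
    """Temporal drift rate (Hz, signed) of a spectro-temporal ripple.

    Fits the ripple phase across log-frequency in consecutive short-time
    spectra; the slope of the unwrapped phase over time is 2*pi*rate with a
    sign telling the drift direction (positive slope = ripple moving toward
    lower frequencies for the sin(rate*t + density*x) convention).
    """
    from scipy.signal import stft

    f, t, z = stft(x, fs=sr, nperseg=2048, noverlap=1536)
    sel = (f >= 500) & (f <= 7000)
    octaves = np.log2(f[sel] / f_low)
    phases = []
    for k in range(z.shape[1]):
        mag_db = 20 * np.log10(np.abs(z[sel, k]) + 1e-12)
        _, amp, phase = fit_sinusoid(octaves, mag_db, density_cpo)
        phases.append(phase)
    inner = slice(2, len(phases) - 2)
    unwrapped = np.unwrap(np.array(phases))[inner]
    slope = np.polyfit(t[inner], unwrapped, 1)[0]
    return slope / (2 * np.pi)
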