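"""Population-rate spectra, rhythm-band detection, and band-pass filtering.

The network's collective oscillation is read off the per-ms histogram of
population spikes: its FFT power spectrum is scanned for the band with the
highest mean power per Hz among the seven conventional cortical rhythms
(delta through the two high-frequency-oscillation bands).  Membrane traces
and local field potentials are isolated into a band with a zero-phase
4th-order Butterworth filter, so ordinal patterns downstream are not
distorted by filter phase.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import signal

__all__ = [
    "BANDS",
    "PowerSpectrum",
    "spike_histogram",
    "power_spectrum",
    "dominant_band",
    "bandpass",
    "band_of_counts",
]

#: Rhythm bands in Hz, half-open intervals (low, high]. Contiguous and
#: non-overlapping; all edges below the 500 Hz Nyquist of 1 kHz sampling.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.2, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
    "hfo1": (100.0, 150.0),
    "hfo2": (150.0, 200.0),
}


class PowerSpectrum(NamedTuple):
    freq: np.ndarray  # Hz
    power: np.ndarray  # squared coefficient magnitude per frequency


def spike_histogram(raster, duration: int) -> np.ndarray:
    """Number of action potentials in the network in each millisecond."""
    t = np.asarray(raster.times if hasattr(raster, "times") else raster, dtype=np.int64)
    if t.size and (t.min() < 0 or t.max() >= duration):
        raise ValueError("raster times must lie within [0, duration)")
    return np.bincount(t, minlength=duration)


def power_spectrum(series, fs: float = 1000.0) -> PowerSpectrum:
    """One-sided FFT power (squared coefficient magnitude) of a demeaned series.

    Interior bins carry the power of both conjugate coefficients, so the total
    equals the full-spectrum sum: sum(power) = N * sum((x - mean)^2) by
    Parseval's identity.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be one-dimensional with at least 2 samples")
    x = x - x.mean()
    coef = np.fft.rfft(x)
    power = np.abs(coef) ** 2
    n = x.size
    # double interior bins (all except DC, and Nyquist when n is even)
    last_unique = power.size - 1 if n % 2 == 0 else power.size
    power[1:last_unique] *= 2.0
    freq = np.fft.rfftfreq(n, d=1.0 / fs)
    return PowerSpectrum(freq=freq, power=power)


def dominant_band(spec: PowerSpectrum, bands: dict[str, tuple[float, float]] = BANDS) -> str:
    """Band containing the maximum mean power per Hz.

    Raises
    ------
    ValueError
        If the spectrum is zero everywhere within the banded range (no
        oscillation to classify).
    """
    best_name, best_density = None, 0.0
    for name, (lo, hi) in bands.items():
        mask = (spec.freq > lo) & (spec.freq <= hi)
        if not mask.any():
            continue
        density = float(spec.power[mask].mean())
        if density > best_density:
            best_name, best_density = name, density
    if best_name is None or best_density == 0.0:
        raise ValueError("spectrum carries no power within the rhythm bands")
    return best_name


def band_of_counts(counts: np.ndarray, fs: float = 1000.0) -> str:
    """Dominant rhythm band of a per-ms population spike histogram."""
    return dominant_band(power_spectrum(counts, fs=fs))


def _sos(band: tuple[float, float] | str, fs: float):
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band edges {band} must satisfy 0 < low < high < fs/2")
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(series, band: tuple[float, float] | str, fs: float = 1000.0, axis: int = 0):
    """Zero-phase band-pass (forward–backward 4th-order Butterworth).

    ``band`` may be a name from :data:`BANDS` or an explicit (low, high) Hz
    pair.  Output has the same length as the input.  Raises ``ValueError``
    when the series is shorter than the filter warm-up.
    """
    x = np.asarray(series, dtype=np.float64)
    sos = _sos(band, fs)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[axis] <= padlen:
        raise ValueError(
            f"series length {x.shape[axis]} too short for the filter warm-up ({padlen} samples)"
        )
    return signal.sosfiltfilt(sos, x, axis=axis)
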