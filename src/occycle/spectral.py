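"""Fourier oscillation statistics and DFT band-pass filtering.

The major period of a uniformly sampled series is the non-DC DFT bin of
maximal power; no zero-padding or spectral interpolation is applied, so
the reported period is quantized to the bin grid (33 samples at 6 min
quantize a 67 min oscillation to the 66 min bin). Significance comes from
a permutation null: the time points are randomly shuffled, which destroys
temporal structure while preserving the marginal distribution. (A cyclic
time shift leaves the power spectrum exactly invariant and therefore
cannot serve as a null for spectrum-based statistics.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OscillationStats:
    major_period_min: float
    amplitude: float
    peak_phase_deg: float
    snr: float
    p_value: float
    major_bin: int


def _spectrum(x: np.ndarray) -> np.ndarray:
    return np.abs(np.fft.rfft(x - x.mean(), axis=-1)) ** 2


def fourier_stats(
    series: np.ndarray,
    sampling_min: float,
    n_perm: int = 1000,
    seed: int | None = 0,
    phase_map=None,
    series_start_min: float = 0.0,
) -> OscillationStats:
    """Oscillation statistics for one uniformly sampled series.

    amplitude = 2|X_k|/n at the major bin k; snr = power at k over the
    median power of the other non-DC bins; the peak phase is the phase
    angle of the fitted cosine's first maximum, mapped through
    ``phase_map`` when given (times in minutes from ``series_start_min``),
    otherwise expressed as a fraction of the major period times 360.
    A constant series returns snr 0 and p 1.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(x) == 0:
        return OscillationStats(np.nan, 0.0, np.nan, 0.0, 1.0, 0)
    power = _spectrum(x)
    k = 1 + int(np.argmax(power[1:]))
    total_min = n * sampling_min
    period = total_min / k
    X = np.fft.rfft(x - x.mean())
    amplitude = 2.0 * np.abs(X[k]) / n
    others = np.delete(power[1:], k - 1)
    med = np.median(others) if len(others) else 0.0
    snr = float(power[k] / med) if med > 0 else np.inf
    # cosine peak time (minutes from the series start)
    peak_t = (-np.angle(X[k]) / (2 * np.pi)) * period % period
    if phase_map is not None:
        peak_phase = float(
            phase_map.phase_of(np.array([(series_start_min + peak_t) * 60.0]))[0]
        )
    else:
        peak_phase = (peak_t / period) * 360.0

    p_value = np.nan
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        obs = power[1:].max()
        exceed = 0
        block = 200
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            perm = rng.permuted(np.tile(x, (b, 1)), axis=1)
            stats = _spectrum(perm)[:, 1:].max(axis=1)
            exceed += int((stats >= obs).sum())
            done += b
        p_value = (1.0 + exceed) / (1.0 + n_perm)
    return OscillationStats(
        major_period_min=float(period),
        amplitude=float(amplitude),
        peak_phase_deg=float(peak_phase),
        snr=snr,
        p_value=float(p_value),
        major_bin=k,
    )


def fourier_stats_matrix(
    values: np.ndarray, sampling_min: float
) -> pd.DataFrame:
    """Vectorized per-row major bin / period / amplitude / snr (no
    permutation p, which is opt-in per series via :func:`fourier_stats`)."""
    x = np.asarray(values, dtype=float)
    n = x.shape[1]
    power = _spectrum(x)
    nz = power[:, 1:]
    k = 1 + np.argmax(nz, axis=1)
    amp = 2.0 * np.sqrt(power[np.arange(len(x)), k]) / n
    # median of the other non-DC bins, per row
    sorted_nz = np.sort(nz, axis=1)
    # remove the max (the major bin) then take the median of the rest
    rest = sorted_nz[:, :-1]
    med = np.median(rest, axis=1)
    snr = np.full(len(x), np.inf)
    ok = med > 0
    snr[ok] = power[np.arange(len(x)), k][ok] / med[ok]
    return pd.DataFrame(
        {
            "major_bin": k,
            "major_period_min": n * sampling_min / k,
            "amplitude": amp,
            "snr": snr,
        }
    )


def bandpass_filter(
    trace: np.ndarray, fs_hz: float, f_osc_hz: float
) -> np.ndarray:
    """Keep DFT bins with f_osc <= |f| <= 4*f_osc (boundaries pass),
    zero everything else including DC, and reconstruct by inverse DFT.

    Idempotent, real-valued output; requires 4*f_osc within Nyquist.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if f_osc_hz <= 0:
        raise ValueError("f_osc must be > 0")
    if 4.0 * f_osc_hz > fs_hz / 2.0:
        raise ValueError("4*f_osc exceeds the Nyquist frequency")
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
    tol = 1e-9 * f_osc_hz
    keep = (freqs >= f_osc_hz - tol) & (freqs <= 4.0 * f_osc_hz + tol)
    X[~keep] = 0.0
    return np.fft.irfft(X, n=n)
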