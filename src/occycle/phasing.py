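"""Respiratory phase angles from the dissolved-oxygen (DO) trace.

The onset of the oxidative phase (steepest DO drop, i.e. first-derivative
minimum) defines 0 deg and the onset of the reductive phase (steepest DO
rise, derivative maximum) defines 94 deg by default; every sample time is
mapped piecewise-linearly between consecutive anchors. The oxidative and
reductive phases differ in duration, which this anchored mapping absorbs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

log = logging.getLogger(__name__)


class PhaseError(RuntimeError):
    """Raised when no usable oscillation can be found in a trace."""


def smooth_do(time_s: np.ndarray, value: np.ndarray,
              window_hz: float = 0.01) -> np.ndarray:
    """Centered running mean with a window of 1/window_hz seconds
    (100 s = 10 samples at the nominal 0.1 Hz); edges shrink the window."""
    time_s = np.asarray(time_s, dtype=float)
    if len(time_s) < 2:
        raise ValueError("trace too short to smooth")
    dt = np.median(np.diff(time_s))
    window = max(1, int(round((1.0 / window_hz) / dt)))
    if len(value) < window:
        raise ValueError(f"trace shorter than the {window}-sample smoothing window")
    return (
        pd.Series(np.asarray(value, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def do_derivative(time_s: np.ndarray, value: np.ndarray) -> np.ndarray:
    """First derivative: central differences, one-sided at the endpoints."""
    return np.gradient(np.asarray(value, float), np.asarray(time_s, float))


def find_anchors(
    time_s: np.ndarray,
    deriv: np.ndarray,
    refractory_frac: float = 0.5,
    min_band_fraction: float = 0.1,
) -> list[tuple[float, str]]:
    """Per-cycle derivative extrema: one ``min_deriv`` and one ``max_deriv``
    anchor per cycle, alternation enforced (earliest wins on ties).

    The expected period comes from the dominant non-DC DFT bin of the
    derivative; candidate extrema closer than ``refractory_frac`` of that
    period are suppressed. Traces whose dominant band carries less than
    ``min_band_fraction`` of the non-DC power (flat or noise-dominated)
    raise :class:`PhaseError`.
    """
    deriv = np.asarray(deriv, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    # below float-noise scale for O(1) traces sampled at 0.1 Hz
    if np.ptp(deriv) < 1e-12:
        raise PhaseError("derivative is flat; no oscillation to anchor")
    x = deriv - deriv.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    if len(power) < 3:
        raise PhaseError("trace too short for anchor detection")
    k = 1 + int(np.argmax(power[1:]))
    band = power[max(1, k - 1): k + 2].sum()
    total = power[1:].sum()
    if total == 0 or band / total < min_band_fraction:
        raise PhaseError(
            "no dominant oscillation in the derivative "
            f"(band fraction {band / total if total else 0:.3f})"
        )
    period_samples = len(x) / k
    distance = max(1, int(round(refractory_frac * period_samples)))
    prominence = 0.2 * np.ptp(deriv)
    # plateau left edges implement the earliest-wins tie-break
    _, pmax = find_peaks(deriv, distance=distance, prominence=prominence,
                         plateau_size=(1, None))
    maxima = pmax["left_edges"]
    _, pmin = find_peaks(-deriv, distance=distance, prominence=prominence,
                         plateau_size=(1, None))
    minima = pmin["left_edges"]
    if len(maxima) == 0 or len(minima) == 0:
        raise PhaseError("fewer than one derivative minimum/maximum detected")

    events = sorted(
        [(i, "min_deriv") for i in minima] + [(i, "max_deriv") for i in maxima]
    )
    # collapse runs of equal kind, keeping the most extreme (first on ties)
    anchors: list[tuple[int, str]] = []
    for idx, kind in events:
        if anchors and anchors[-1][1] == kind:
            prev = anchors[-1][0]
            better = deriv[idx] > deriv[prev] if kind == "max_deriv" else deriv[idx] < deriv[prev]
            if better:
                anchors[-1] = (idx, kind)
        else:
            anchors.append((idx, kind))
    if len(anchors) < 2:
        raise PhaseError("need at least one min/max anchor pair")
    return [(float(time_s[i]), kind) for i, kind in anchors]


@dataclass
class PhaseMap:
    """Piecewise-linear map from time to respiratory phase angle."""

    anchors: list[tuple[float, str]]
    sample_times: np.ndarray
    phase_deg: np.ndarray       # NaN outside the anchored span
    cycle_index: np.ndarray     # -1 outside the anchored span
    reductive_anchor_deg: float = 94.0

    def phase_of(self, times: np.ndarray) -> np.ndarray:
        phase, _ = _phase_at(np.asarray(times, float), self.anchors,
                             self.reductive_anchor_deg)
        return phase

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.sample_times,
                "phase_deg": self.phase_deg,
                "cycle_index": self.cycle_index,
            }
        )


def _phase_at(times: np.ndarray, anchors: list[tuple[float, str]],
              reductive_deg: float) -> tuple[np.ndarray, np.ndarray]:
    a_times = np.array([t for t, _ in anchors])
    a_kinds = [k for _, k in anchors]
    phase = np.full(times.shape, np.nan)
    cycle = np.full(times.shape, -1, dtype=int)
    # cycle index = number of min_deriv anchors passed, counting from 0
    min_times = a_times[[k == "min_deriv" for k in a_kinds]]
    seg = np.searchsorted(a_times, times, side="right") - 1
    inside = (seg >= 0) & (times <= a_times[-1]) & (seg < len(a_times))
    seg_in = np.clip(seg, 0, len(a_times) - 2)
    at_last = inside & (times == a_times[-1])
    for i in np.where(inside)[0]:
        s = seg_in[i] if not at_last[i] else len(a_times) - 2
        t0, t1 = a_times[s], a_times[s + 1]
        frac = 0.0 if t1 == t0 else (times[i] - t0) / (t1 - t0)
        if a_kinds[s] == "min_deriv":
            phase[i] = frac * reductive_deg
        else:
            phase[i] = reductive_deg + frac * (360.0 - reductive_deg)
        phase[i] = phase[i] % 360.0
        cycle[i] = np.searchsorted(min_times, times[i], side="right") - 1
    return phase, cycle


def assign_phase(
    sample_times: np.ndarray,
    anchors: list[tuple[float, str]],
    reductive_anchor_deg: float = 94.0,
) -> PhaseMap:
    """Map sample times onto respiratory phase angles.

    Within each cycle, time maps linearly min_deriv -> max_deriv onto
    0 -> ``reductive_anchor_deg`` and max_deriv -> next min_deriv onto
    ``reductive_anchor_deg`` -> 360. Samples outside the anchored span get
    NaN phase and are logged; they are excluded from cycle averaging
    downstream rather than extrapolated.
    """
    kinds = [k for _, k in anchors]
    if any(a == b for a, b in zip(kinds, kinds[1:])):
        raise ValueError("anchors must alternate min_deriv/max_deriv")
    sample_times = np.asarray(sample_times, dtype=float)
    phase, cycle = _phase_at(sample_times, anchors, reductive_anchor_deg)
    n_out = int(np.isnan(phase).sum())
    if n_out:
        log.warning("%d samples fall outside the anchored span; phase set NaN",
                    n_out)
    return PhaseMap(
        anchors=list(anchors),
        sample_times=sample_times,
        phase_deg=phase,
        cycle_index=cycle,
        reductive_anchor_deg=reductive_anchor_deg,
    )


def phase_from_do(
    time_s: np.ndarray,
    do_value: np.ndarray,
    sample_times: np.ndarray,
    reductive_anchor_deg: float = 94.0,
    window_hz: float = 0.01,
    refractory_frac: float = 0.5,
) -> PhaseMap:
    """Convenience chain: smooth -> derivative -> anchors -> phase map."""
    smooth = smooth_do(time_s, do_value, window_hz=window_hz)
    deriv = do_derivative(time_s, smooth)
    anchors = find_anchors(time_s, deriv, refractory_frac=refractory_frac)
    return assign_phase(sample_times, anchors, reductive_anchor_deg)
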