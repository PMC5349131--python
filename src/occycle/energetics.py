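"""Cellular energy state and inferred chromatin-remodeler activity.

ATP-dependent remodelers of the ISWI family are product-inhibited by ADP;
with a Michaelis constant Km for ATP and a competitive inhibition constant
Ki for ADP the relative activity is

    v / Vmax = [ATP] / (Km * (1 + [ADP]/Ki) + [ATP])

Defaults Km = 0.15 mM and Ki = 0.1 mM are in-vitro values for ISWI. The
adenylate energy charge is the Atkinson index
(ATP + ADP/2) / (ATP + ADP + AMP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KineticParams:
    km_mm: float = 0.15
    ki_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.km_mm <= 0 or self.ki_mm <= 0:
            raise ValueError("Km and Ki must be > 0")


def remodeling_activity(
    atp_mm: np.ndarray | float,
    adp_mm: np.ndarray | float,
    params: KineticParams = KineticParams(),
) -> np.ndarray | float:
    """Relative remodeler activity v/Vmax in [0, 1) under competitive
    product inhibition by ADP. Zero ATP gives zero activity."""
    atp = np.asarray(atp_mm, dtype=float)
    adp = np.asarray(adp_mm, dtype=float)
    if np.any(atp < 0) or np.any(adp < 0):
        raise ValueError("concentrations must be >= 0")
    out = atp / (params.km_mm * (1.0 + adp / params.ki_mm) + atp)
    return out if out.ndim else float(out)


def energy_charge(
    atp_mm: np.ndarray | float,
    adp_mm: np.ndarray | float,
    amp_mm: np.ndarray | float,
) -> np.ndarray | float:
    """Adenylate energy charge (ATP + ADP/2) / (ATP + ADP + AMP) in [0, 1].

    All-zero pools are undefined and return NaN.
    """
    atp = np.asarray(atp_mm, dtype=float)
    adp = np.asarray(adp_mm, dtype=float)
    amp = np.asarray(amp_mm, dtype=float)
    total = atp + adp + amp
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, (atp + adp / 2.0) / np.where(total > 0, total, 1.0),
                       np.nan)
    return out if out.ndim else float(out)


def phase_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r between two cycle profiles on the common phase grid, with
    a two-sided p-value from the cyclic-shift null.

    Cycle profiles are strongly autocorrelated, so the null rotates one
    profile through all grid offsets (including 0) and counts offsets with
    |r| at least the observed one; with a 24-point grid the smallest
    attainable p is 1/24.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and on a common grid")
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant profile has no defined correlation")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xc * yc))
    r_shifts = np.array([np.mean(xc * np.roll(yc, k)) for k in range(n)])
    p = float(np.mean(np.abs(r_shifts) >= np.abs(r_obs) - 1e-12))
    return r_obs, p


def normalize_to_reference(
    signal: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """log2(signal/reference) per timepoint; nonpositive reference or
    signal values yield NaN (flagged missing) rather than fabricated
    ratios."""
    sig = np.asarray(signal, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sig.shape != ref.shape:
        raise ValueError("signal and reference must share timepoints")
    ok = (sig > 0) & (ref > 0)
    out = np.full(sig.shape, np.nan)
    out[ok] = np.log2(sig[ok] / ref[ok])
    return out
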