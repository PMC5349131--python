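"""Average-cycle profiles on the 15-degree phase grid.

Observations from several respiratory cycles are pooled by phase angle,
smoothed with a cubic regression spline whose flexibility matches the
number of samples per cycle, and resampled at 24 points (every 15 deg).
Approximate periodicity is enforced by replicating the data at +-360 deg
before fitting, so the spline sees a full cycle of context on both sides
of the [0, 360) window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

log = logging.getLogger(__name__)

PHASE_GRID = np.arange(0.0, 360.0, 15.0)

ANABOLIC_CLUSTERS = ("A", "AB", "B", "B.C", "B.D", "ab.n")
CATABOLIC_CLUSTERS = ("C", "D", "cd.n", "cd.ab")


def df_for(period_min: float, sampling_min: float) -> int:
    """Spline degrees of freedom: samples per respiratory cycle."""
    return int(round(period_min / sampling_min))


def fit_cycle(
    values: np.ndarray,
    phases_deg: np.ndarray,
    df: int,
    grid: np.ndarray = PHASE_GRID,
) -> pd.Series:
    """Fit one variable's pooled (phase, value) points and evaluate on the
    phase grid.

    ``df`` effective degrees of freedom are realized as a least-squares
    cubic spline with uniform interior knots every 360/df degrees over the
    replicated range; the fit is linear in the data. NaN observations are
    dropped.
    """
    values = np.asarray(values, dtype=float)
    phases = np.asarray(phases_deg, dtype=float) % 360.0
    ok = np.isfinite(values) & np.isfinite(phases)
    values, phases = values[ok], phases[ok]
    n = len(values)
    if df < 4:
        raise ValueError("cubic spline needs df >= 4")
    if df > n:
        raise ValueError(f"df={df} exceeds the {n} available observations")
    x = np.concatenate([phases - 360.0, phases, phases + 360.0])
    y = np.tile(values, 3)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    knots = np.linspace(-360.0, 720.0, 3 * df + 1)[1:-1]
    knots = knots[(knots > x[0]) & (knots < x[-1])]
    try:
        spl = LSQUnivariateSpline(x, y, knots, k=3)
    except ValueError as err:  # Schoenberg-Whitney violation: sparse coverage
        raise ValueError(
            "phase coverage too sparse for the requested df; "
            "reduce df or supply more samples"
        ) from err
    return pd.Series(spl(grid), index=pd.Index(grid, name="phase_deg"))


def fit_cycle_frame(
    values: pd.DataFrame, phases_deg: np.ndarray, df: int
) -> pd.DataFrame:
    """fit_cycle applied to every row of a (series x timepoint) frame."""
    out = {
        name: fit_cycle(row.to_numpy(), phases_deg, df)
        for name, row in values.iterrows()
    }
    return pd.DataFrame(out).T.rename_axis(values.index.name)


def _wrapped_step(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Forward phase step from a to b in (0, 360]."""
    return (b - a) % 360.0


def rate_of_change(
    values: np.ndarray,
    phases_deg: np.ndarray,
    df: int,
    per_deg: float = 15.0,
) -> pd.Series:
    """Rate-of-change cycle profile in units of change per ``per_deg``
    degrees of phase.

    Consecutive differences are taken in time order (the inputs' order),
    assigned the circular midpoint of the two sample phases, rescaled from
    per-sample to per-15-degree units, and cycle-fitted.
    """
    values = np.asarray(values, dtype=float)
    phases = np.asarray(phases_deg, dtype=float) % 360.0
    if len(values) < 3:
        raise ValueError("need at least 3 samples for a rate profile")
    diffs = np.diff(values)
    steps = _wrapped_step(phases[:-1], phases[1:])
    mids = (phases[:-1] + steps / 2.0) % 360.0
    mean_step = steps[np.isfinite(steps)].mean()
    if not np.isfinite(mean_step) or mean_step == 0:
        raise ValueError("cannot determine the mean inter-sample phase step")
    scaled = diffs * (per_deg / mean_step)
    return fit_cycle(scaled, mids, df)


def sum_clusters(
    expr: pd.DataFrame, labels: pd.Series, with_superclusters: bool = True
) -> pd.DataFrame:
    """Summed transcript abundance per cluster (rows) over timepoints.

    Adds ``anabolic``/``catabolic`` supercluster sums (clusters A, AB, B
    plus the merged B.C/B.D/ab.n variants vs C, D, cd.n, cd.ab). Clusters
    named in the labels but empty in the expression table yield a zero
    series with a warning.
    """
    cluster_names = pd.unique(labels.dropna())
    labels = labels.reindex(expr.index)
    sums = {}
    for cl in cluster_names:
        members = expr.loc[labels == cl]
        if members.empty:
            log.warning("cluster %s has no genes in the expression table", cl)
            sums[cl] = pd.Series(0.0, index=expr.columns)
        else:
            sums[cl] = members.sum(axis=0)
    out = pd.DataFrame(sums).T
    if with_superclusters:
        ana = labels.isin(ANABOLIC_CLUSTERS)
        cat = labels.isin(CATABOLIC_CLUSTERS)
        out.loc["anabolic"] = expr.loc[ana].sum(axis=0)
        out.loc["catabolic"] = expr.loc[cat].sum(axis=0)
    out.index.name = "cluster"
    return out


def subtract_temporal_mean(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Center each series (column) on its mean over the phase grid.

    Returns the centered profiles and the removed means (the "side bar"
    averages), so input == centered + means exactly.
    """
    means = profiles.mean(axis=0)
    means.name = "temporal_mean"
    return profiles - means, means
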