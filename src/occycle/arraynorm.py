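"""Tiling-array normalization and DNA-occupancy computation.

The procedure follows the least-variant-set (LVS) idea: probes whose log2
intensity is nearly constant across all arrays in both the pDNA and gDNA
channels anchor a per-array LOESS correction; strand-paired probes are
then averaged, the MNase digestion bias is estimated from the mDNA/gDNA
control contrast, and occupancy is

    DNA occ(p, t) = log2 pDNA(p, t) - log2 gDNA(p, t) - bias(p)

Intensities are stored linear and positive; values <= 0 are treated as
missing (NaN after log transform) rather than clipped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import PROBE_META_COLS, array_columns

log = logging.getLogger(__name__)

_MIN_LVS = 10  # smallest LVS set the LOESS smoother will accept
_MAX_FIT_POINTS = 2000  # LVS subsample cap for the local regression
_N_EVAL_POINTS = 200    # quantile grid on which the LOESS curve is evaluated


def _probe_key(table: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(table[["probe_id", "strand"]])


def log2_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """log2 of the array columns; nonpositive intensities become NaN."""
    vals = table[array_columns(table)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return pd.DataFrame(out, columns=array_columns(table), index=table.index)


def select_least_variant(
    pdna: pd.DataFrame, gdna: pd.DataFrame, threshold: float = 0.1
) -> pd.Index:
    """Probes whose log2-intensity variance across arrays is below
    ``threshold`` in both channels.

    Returns a (probe_id, strand) MultiIndex. Raises if the set is empty.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    keys_p, keys_g = _probe_key(pdna), _probe_key(gdna)
    common = keys_p.intersection(keys_g)
    var_p = log2_intensities(pdna).set_axis(keys_p).var(axis=1, ddof=1)
    var_g = log2_intensities(gdna).set_axis(keys_g).var(axis=1, ddof=1)
    sel = common[(var_p.loc[common] < threshold) & (var_g.loc[common] < threshold)]
    if len(sel) == 0:
        raise ValueError(
            f"no probe has variance < {threshold} in both channels; "
            "increase the LVS threshold"
        )
    return sel


def loess_normalize(
    table: pd.DataFrame, lvs: pd.Index, span: float = 0.3
) -> pd.DataFrame:
    """Per-array LOESS normalization against the across-array mean.

    For each array the deviation of its log2 intensities from the row-mean
    reference is smoothed (locally weighted linear regression, no
    robustness iterations, so the smoother is linear in the data) as a
    function of the reference level on the LVS probes only, evaluated at
    every probe by interpolation, and subtracted. A final recentering pins
    the mean LVS deviation at zero.
    """
    keys = _probe_key(table)
    in_lvs = keys.isin(lvs)
    if in_lvs.sum() < _MIN_LVS:
        raise ValueError(
            f"only {int(in_lvs.sum())} LVS probes present; "
            f"need at least {_MIN_LVS} for the LOESS smoother"
        )
    log2 = log2_intensities(table).to_numpy()
    ref = np.nanmean(log2, axis=1)
    out = table.copy()
    order = np.argsort(ref[in_lvs], kind="stable")
    x_lvs = ref[in_lvs][order]
    # bound the local-regression cost on large LVS sets: fit on an
    # even-rank subsample and evaluate on a quantile grid, then interpolate
    lvs_rows = np.arange(len(x_lvs))
    if len(x_lvs) > _MAX_FIT_POINTS:
        lvs_rows = np.linspace(0, len(x_lvs) - 1, _MAX_FIT_POINTS).astype(int)
    x_fit = x_lvs[lvs_rows]
    n_eval = min(len(x_fit), _N_EVAL_POINTS)
    x_eval = np.quantile(x_fit, np.linspace(0, 1, n_eval))
    for j, col in enumerate(array_columns(table)):
        d_lvs = (log2[in_lvs, j] - ref[in_lvs])[order]
        fitted = lowess(
            d_lvs[lvs_rows], x_fit, frac=span, it=0, return_sorted=False,
            xvals=x_eval,
        )
        corr = np.interp(ref, x_eval, fitted)
        corrected = log2[:, j] - corr
        corrected -= np.nanmean(corrected[in_lvs] - ref[in_lvs])
        out[col] = np.exp2(corrected)
    return out


def average_strand_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Average forward/reverse probe pairs sharing (chrom, start, end).

    Averaging is done on log2 intensities. Unpaired probes are kept as-is
    with a logged warning; the output carries one row per position with
    strand '.'.
    """
    cols = array_columns(table)
    log2 = log2_intensities(table)
    work = table[PROBE_META_COLS].copy()
    work[cols] = log2
    grouped = work.groupby(["chrom", "start", "end"], sort=True)
    n_unpaired = int((grouped.size() != 2).sum())
    if n_unpaired:
        log.warning("%d probe positions are not strand pairs; kept unaveraged",
                    n_unpaired)
    agg = grouped.agg({"probe_id": "first", **{c: "mean" for c in cols}}).reset_index()
    agg["strand"] = "."
    agg[cols] = np.exp2(agg[cols].to_numpy(dtype=float))
    return agg[PROBE_META_COLS + cols]


def compute_mnase_bias(mdna: pd.DataFrame, gdna: pd.DataFrame) -> pd.Series:
    """Per-probe MNase digestion bias.

    bias(p) = mean over mDNA arrays of log2 intensity
            - mean over gDNA arrays of log2 intensity.

    Probes missing from either table are excluded (logged).
    """
    m_log2 = log2_intensities(mdna).set_axis(pd.Index(mdna["probe_id"]))
    g_log2 = log2_intensities(gdna).set_axis(pd.Index(gdna["probe_id"]))
    common = m_log2.index.intersection(g_log2.index)
    dropped = (len(m_log2) - len(common)) + (len(g_log2) - len(common))
    if dropped:
        log.warning("%d probes missing from one channel; excluded from bias",
                    dropped)
    bias = m_log2.loc[common].mean(axis=1) - g_log2.loc[common].mean(axis=1)
    bias.name = "bias"
    return bias


def compute_occupancy(
    pdna: pd.DataFrame, gdna: pd.DataFrame, bias: pd.Series
) -> pd.DataFrame:
    """occ(p, t) = log2 pDNA - log2 gDNA - bias, per probe and timepoint.

    Expects normalized, strand-averaged tables with matching array columns
    (one per timepoint, same order). Probes without a bias estimate are
    dropped; nonpositive intensities yield NaN at that timepoint.
    """
    cols_p, cols_g = array_columns(pdna), array_columns(gdna)
    if len(cols_p) != len(cols_g):
        raise ValueError("pDNA and gDNA must have matched arrays per timepoint")
    p = log2_intensities(pdna).set_axis(pd.Index(pdna["probe_id"]))
    g = log2_intensities(gdna).set_axis(pd.Index(gdna["probe_id"]))
    common = p.index.intersection(g.index).intersection(bias.index)
    occ = (
        p.loc[common].to_numpy()
        - g.loc[common, cols_g].to_numpy()
        - bias.loc[common].to_numpy()[:, None]
    )
    meta = pdna.set_index("probe_id").loc[common, ["chrom", "start", "end", "strand"]]
    out = meta.reset_index()
    out[cols_p] = occ
    return out
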