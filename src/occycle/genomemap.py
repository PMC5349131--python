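"""TSS- and dyad-relative occupancy profiles and nucleosome classification.

Probes are re-indexed to signed distances from each gene's TSS (upstream
negative, strand-aware) or from each nucleosome dyad. Dyads are labeled by
ordinal position along the transcription direction: the first dyad at or
downstream of the TSS footprint is +1, the last genic dyad is terminal,
+2 through the penultimate are gene-body (GB), and the nearest dyad
upstream of the NDR is -1. The NDR-flanking set {-1, +1, terminal} forms
the "TSS" analysis class, everything else the "GB" class.

Profile medians are taken over genes, not probes: probes sharing a
position bin within one gene are averaged first.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import array_columns, probe_midpoints
from .simulate import NUC_HALF_BP

log = logging.getLogger(__name__)


def map_probes_to_tss(
    probes: pd.DataFrame,
    annotations: pd.DataFrame,
    half_window: int = 1000,
) -> pd.DataFrame:
    """Index probes by signed TSS-relative position per gene.

    Returns long-format (gene_id, probe_id, rel_pos) for probes whose
    midpoint lies within ``half_window`` bp of the TSS; rel_pos is
    (midpoint - TSS) on + strand genes and (TSS - midpoint) on - strand
    genes, so upstream is negative for both.
    """
    mids = probe_midpoints(probes)
    rows = []
    for chrom, ann in annotations.groupby("chrom"):
        mask = probes["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        cmids = mids[mask]
        cidx = np.where(mask)[0]
        order = np.argsort(cmids, kind="stable")
        cmids_s, cidx_s = cmids[order], cidx[order]
        for _, g in ann.iterrows():
            lo = np.searchsorted(cmids_s, g["tss"] - half_window, side="left")
            hi = np.searchsorted(cmids_s, g["tss"] + half_window, side="right")
            if hi <= lo:
                continue
            sel = cidx_s[lo:hi]
            sign = 1.0 if g["strand"] == "+" else -1.0
            rel = sign * (cmids_s[lo:hi] - g["tss"])
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": g["gene_id"],
                        "probe_row": sel,
                        "probe_id": probes["probe_id"].to_numpy()[sel],
                        "rel_pos": rel,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "probe_row", "probe_id", "rel_pos"])
    return pd.concat(rows, ignore_index=True)


def _infer_bin(occupancy: pd.DataFrame) -> int:
    starts = np.sort(occupancy["start"].unique())
    if len(starts) < 2:
        return 1
    return int(np.median(np.diff(starts)))


def median_tss_profile(
    occupancy: pd.DataFrame,
    tss_index: pd.DataFrame,
    bin_bp: int | None = None,
) -> pd.DataFrame:
    """Median occupancy over genes by TSS-relative position bin and
    timepoint.

    ``bin_bp`` defaults to the probe spacing inferred from the occupancy
    table. Probes in the same bin within a gene are averaged before the
    across-gene median (genes, not probes, are the units).
    """
    if tss_index.empty:
        raise ValueError("no probes mapped to any TSS")
    cols = array_columns(occupancy)
    bin_bp = bin_bp or _infer_bin(occupancy)
    vals = occupancy[cols].to_numpy()
    merged = tss_index.copy()
    merged["bin"] = (np.round(merged["rel_pos"] / bin_bp) * bin_bp).astype(int)
    data = pd.DataFrame(vals[merged["probe_row"].to_numpy()], columns=cols)
    data["gene_id"] = merged["gene_id"].to_numpy()
    data["bin"] = merged["bin"].to_numpy()
    per_gene = data.groupby(["gene_id", "bin"], sort=False).mean()
    profile = per_gene.groupby("bin").median().sort_index()
    profile.index.name = "rel_pos"
    return profile


def classify_dyads(
    dyads: pd.DataFrame,
    annotations: pd.DataFrame,
    upstream_cutoff: int = 1000,
    tss_cover_bp: int = NUC_HALF_BP,
) -> pd.DataFrame:
    """Assign dyads to genes and label them by ordinal position.

    A dyad is a candidate for a gene if it lies within ``upstream_cutoff``
    bp upstream of the TSS or inside the transcript; ambiguous dyads go to
    the closer TSS (ties to the + strand gene). Ordinals run along the
    transcription direction over dyads at rel >= -``tss_cover_bp`` (so a
    dyad covering the TSS is +1); the nearest strictly-upstream dyad is
    -1. Classes: upstream (-1), TSS (+1), terminal (last genic, when a
    gene has >= 2 genic dyads), GB otherwise; the analysis_class column
    groups {upstream, TSS, terminal} as "TSS" and the rest as "GB". Genes
    with no genic dyad are excluded (logged).
    """
    cand = []
    for chrom, ann in annotations.groupby("chrom"):
        dsub = dyads[dyads["chrom"] == chrom]
        if dsub.empty:
            continue
        pos = dsub["pos"].to_numpy()
        for _, g in ann.iterrows():
            sign = 1 if g["strand"] == "+" else -1
            rel = sign * (pos - g["tss"])
            length = abs(int(g["transcript_end"]) - int(g["tss"])) + 1
            keep = (rel >= -upstream_cutoff) & (rel < length)
            if not keep.any():
                continue
            cand.append(
                pd.DataFrame(
                    {
                        "dyad_row": dsub.index.to_numpy()[keep],
                        "pos": pos[keep],
                        "chrom": chrom,
                        "gene_id": g["gene_id"],
                        "strand": g["strand"],
                        "rel": rel[keep],
                        "dist_tss": np.abs(rel[keep]),
                    }
                )
            )
    if not cand:
        raise ValueError("no dyad lies near any annotated gene")
    cand = pd.concat(cand, ignore_index=True)
    cand["strand_rank"] = (cand["strand"] != "+").astype(int)  # ties -> + strand
    cand = (
        cand.sort_values(["dyad_row", "dist_tss", "strand_rank", "gene_id"],
                         kind="stable")
        .drop_duplicates("dyad_row")
    )

    out = []
    for gid, grp in cand.groupby("gene_id"):
        grp = grp.sort_values("rel", kind="stable")
        genic = grp[grp["rel"] >= -tss_cover_bp]
        upstream = grp[grp["rel"] < -tss_cover_bp]
        if genic.empty:
            log.warning("gene %s has no genic dyad; excluded", gid)
            continue
        ordinals = np.arange(1, len(genic) + 1)
        n_genic = len(genic)
        classes = []
        for o in ordinals:
            if o == 1:
                classes.append("TSS")
            elif o == n_genic:
                classes.append("terminal")
            else:
                classes.append("GB")
        rec = genic.assign(ordinal=ordinals, cls=classes)
        if not upstream.empty:
            minus1 = upstream.iloc[[-1]].assign(ordinal=-1, cls="upstream")
            rec = pd.concat([minus1, rec])
        out.append(rec)
    res = pd.concat(out, ignore_index=True)
    res["analysis_class"] = np.where(res["cls"].isin(["upstream", "TSS", "terminal"]),
                                     "TSS", "GB")
    return res[["chrom", "pos", "gene_id", "strand", "rel", "ordinal", "cls",
                "analysis_class"]]


def _dyad_relative_index(
    occupancy: pd.DataFrame,
    classification: pd.DataFrame,
    half_window: int,
) -> pd.DataFrame:
    """Long (dyad, probe) pairs with strand-aware relative positions."""
    mids = probe_midpoints(occupancy)
    rows = []
    for chrom, dsub in classification.groupby("chrom"):
        mask = occupancy["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        cmids = mids[mask]
        cidx = np.where(mask)[0]
        order = np.argsort(cmids, kind="stable")
        cmids_s, cidx_s = cmids[order], cidx[order]
        for _, d in dsub.iterrows():
            lo = np.searchsorted(cmids_s, d["pos"] - half_window, side="left")
            hi = np.searchsorted(cmids_s, d["pos"] + half_window, side="right")
            if hi <= lo:
                continue
            sign = 1.0 if d["strand"] == "+" else -1.0
            rel = sign * (cmids_s[lo:hi] - d["pos"])
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": d["gene_id"],
                        "analysis_class": d["analysis_class"],
                        "cls": d["cls"],
                        "probe_row": cidx_s[lo:hi],
                        "rel_pos": rel,
                    }
                )
            )
    if not rows:
        raise ValueError("no probes within the dyad windows")
    return pd.concat(rows, ignore_index=True)


def dyad_aligned_profile(
    occupancy: pd.DataFrame,
    classification: pd.DataFrame,
    half_window: int = 500,
    bin_bp: int | None = None,
    class_col: str = "analysis_class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median occupancy aligned to nucleosome dyads, by class.

    Returns ``(positional, central)``: positional is long-format
    (class, rel_pos, timepoint, median); central is a class x timepoint
    frame of medians over the dyad footprint (+- 73 bp), the input for
    temporal ("Fig. 3A"-style) analyses. Classes with no dyads simply do
    not appear (a warning is logged when the classification is empty for
    a requested class column).
    """
    cols = array_columns(occupancy)
    bin_bp = bin_bp or _infer_bin(occupancy)
    idx = _dyad_relative_index(occupancy, classification, half_window)
    vals = occupancy[cols].to_numpy()
    data = pd.DataFrame(vals[idx["probe_row"].to_numpy()], columns=cols)
    data["gene_id"] = idx["gene_id"].to_numpy()
    data["cls"] = idx[class_col].to_numpy()
    data["bin"] = (np.round(idx["rel_pos"].to_numpy() / bin_bp) * bin_bp).astype(int)

    per_gene = data.groupby(["cls", "gene_id", "bin"], sort=False).mean()
    positional = (
        per_gene.groupby(["cls", "bin"]).median()
        .rename_axis(["cls", "rel_pos"])
        .melt(ignore_index=False, var_name="timepoint", value_name="median")
        .reset_index()
    )

    central_rows = data[np.abs(data["bin"]) <= NUC_HALF_BP]
    per_gene_c = central_rows.groupby(["cls", "gene_id"], sort=False)[cols].mean()
    central = per_gene_c.groupby("cls").median()
    return positional, central


def cluster_profiles(
    occupancy: pd.DataFrame,
    classification: pd.DataFrame,
    cluster_labels: pd.Series,
    half_window: int = 500,
    bin_bp: int | None = None,
    merge_expanded_b: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-expression-cluster dyad-aligned medians.

    Returns ``(positional, central)`` as in :func:`dyad_aligned_profile`,
    grouped by each gene's cluster label instead of nucleosome class.
    ``merge_expanded_b`` folds the differential clusters B.C and B.D into
    an expanded cluster B. Genes without a label are skipped; empty
    clusters are logged and omitted.
    """
    labels = cluster_labels.dropna().astype(str)
    if merge_expanded_b:
        labels = labels.replace({"B.C": "B", "B.D": "B"})
    cls = classification.merge(
        labels.rename("cluster"), left_on="gene_id", right_index=True, how="inner"
    )
    missing = set(labels.unique()) - set(cls["cluster"].unique())
    for m in sorted(missing):
        log.warning("cluster %s has no classified dyads; omitted", m)
    if cls.empty:
        raise ValueError("no classified dyad carries a cluster label")
    cls = cls.assign(analysis_class=cls["cluster"])
    return dyad_aligned_profile(
        occupancy, cls, half_window=half_window, bin_bp=bin_bp,
        class_col="analysis_class",
    )
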