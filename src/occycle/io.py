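"""Readers and writers for the plain-text formats used throughout the package.

All genomic coordinates are 1-based inclusive in memory (GFF convention);
BED files are converted to/from half-open 0-based at the boundary.

Probe tables are TSV with the metadata columns ``probe_id, chrom, start,
end, strand`` followed by one positive-intensity column per array, in
sample-time order.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_META_COLS = ["probe_id", "chrom", "start", "end", "strand"]

_GFF_COLS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "frame", "attributes",
]


def array_columns(table: pd.DataFrame) -> list[str]:
    """Array (intensity or occupancy) columns of a probe table, in order."""
    return [c for c in table.columns if c not in PROBE_META_COLS]


def probe_midpoints(table: pd.DataFrame) -> np.ndarray:
    return (table["start"].to_numpy() + table["end"].to_numpy()) / 2.0


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} lacks columns {missing}")
    return df


def write_probe_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read gene annotations from GFF3 into (gene_id, chrom, TSS, strand,
    transcript_end, cluster)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLS, header=None, dtype={"seqid": str}
    )
    df = df[df["type"] == "gene"].copy()

    def _attr(attrs: str, key: str) -> str | None:
        m = re.search(rf"(?:^|;){key}=([^;]+)", attrs)
        return m.group(1) if m else None

    gene_id = df["attributes"].map(lambda a: _attr(a, "ID"))
    cluster = df["attributes"].map(lambda a: _attr(a, "cluster"))
    plus = df["strand"].to_numpy() == "+"
    out = pd.DataFrame(
        {
            "gene_id": gene_id.to_numpy(),
            "chrom": df["seqid"].to_numpy(),
            "tss": np.where(plus, df["start"], df["end"]),
            "transcript_end": np.where(plus, df["end"], df["start"]),
            "strand": df["strand"].to_numpy(),
            "cluster": cluster.to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    plus = annotations["strand"] == "+"
    start = np.where(plus, annotations["tss"], annotations["transcript_end"])
    end = np.where(plus, annotations["transcript_end"], annotations["tss"])
    attrs = "ID=" + annotations["gene_id"].astype(str)
    has_cluster = annotations["cluster"].notna()
    attrs = attrs.where(
        ~has_cluster, attrs + ";cluster=" + annotations["cluster"].astype(str)
    )
    gff = pd.DataFrame(
        {
            "seqid": annotations["chrom"],
            "source": "occycle",
            "type": "gene",
            "start": start.astype(int),
            "end": end.astype(int),
            "score": ".",
            "strand": annotations["strand"],
            "frame": ".",
            "attributes": attrs,
        }
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        gff.to_csv(fh, sep="\t", index=False, header=False)


def read_dyads(path: str | Path) -> pd.DataFrame:
    """Read dyad positions from BED; returns (chrom, pos) with pos 1-based."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({"chrom": df[0].astype(str), "pos": df[2].astype(int)})
    return out


def write_dyads(dyads: pd.DataFrame, path: str | Path) -> None:
    name = dyads["gene_id"] if "gene_id" in dyads.columns else "."
    bed = pd.DataFrame(
        {
            "chrom": dyads["chrom"],
            "start": dyads["pos"].astype(int) - 1,
            "end": dyads["pos"].astype(int),
            "name": name,
            "score": 0,
            "strand": dyads["strand"] if "strand" in dyads.columns else ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    """Two-column CSV trace (time_s, value)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"trace {path} needs two columns (time_s, value)")
    df.columns = ["time_s", "value", *df.columns[2:]]
    return df


def write_trace(time_s: np.ndarray, value: np.ndarray, path: str | Path,
                value_name: str = "value") -> None:
    pd.DataFrame({"time_s": time_s, value_name: value}).to_csv(path, index=False)


def read_series_table(path: str | Path, index_col: str | int = 0) -> pd.DataFrame:
    """Generic TSV matrix (rows = genes/variables, columns = timepoints)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_series_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
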