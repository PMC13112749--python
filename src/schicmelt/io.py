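"""Text I/O: the pairs dialect, bedGraph/BED tracks and TSV tables.

Pairs dialect: tab-separated, header lines starting ``#``, columns
readID chrom1 pos1 chrom2 pos2 strand1 strand2 cellID [category
duplicate ...]; positions 1-based.  Fragment maps and boundaries are BED
(0-based half-open); scalar tracks are bedGraph.
"""

from __future__ import annotations

import pandas as pd

PAIRS_BASE_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2",
                      "strand1", "strand2", "cell_id"]
_HEADER_NAMES = {"read_id": "readID", "cell_id": "cellID"}


def write_pairs(pairs: pd.DataFrame, path, extra_columns: list[str] | None = None) -> None:
    cols = PAIRS_BASE_COLUMNS + [c for c in (extra_columns or [])
                                 if c in pairs.columns]
    cols += [c for c in ("mapq1", "mapq2", "category", "duplicate")
             if c in pairs.columns and c not in cols]
    with open(path, "w") as fh:
        fh.write("## pairs-dialect v1\n")
        fh.write("#columns: " + " ".join(_HEADER_NAMES.get(c, c) for c in cols) + "\n")
        pairs[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path) -> pd.DataFrame:
    names = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("#columns:"):
                rev = {v: k for k, v in _HEADER_NAMES.items()}
                names = [rev.get(c, c) for c in line.split(":", 1)[1].split()]
    if names is None:
        names = PAIRS_BASE_COLUMNS
    return pd.read_csv(path, sep="\t", skiprows=skip, names=names)


def write_bedgraph(track: pd.DataFrame, path, value_col: str = "score") -> None:
    t = track.dropna(subset=[value_col])
    t[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "score"])


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
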