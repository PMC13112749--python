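"""Melting/concretion state calling and the KS melting statistic.

For a region of interest (typically a long B-compartment gene), cells are
clustered on their z-scaled per-bin insulation scores (Ward linkage, two
clusters); the cluster with the lower median insulation is the melting
state.  The degree of melting of the region is the one-sided
Kolmogorov-Smirnov maximum distance D between the pooled (cell, bin)
insulation-score distributions of the two clusters, with the asymptotic
one-sided p-value p = exp(-2 D^2 mn/(m+n)) and significance at
p < 1e-5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .matrix import bin_contacts
from .tracks import InsulationParams, insulation_scores

P_SIGNIFICANT = 1e-5


@dataclass(frozen=True)
class RegionOfInterest:
    label: str
    chrom: str
    start: int
    end: int
    compartment: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    def bin_range(self, bin_size: int) -> tuple[int, int]:
        """Covering bin span, rounded outward to the bin grid."""
        return self.start // bin_size, -(-self.end // bin_size)


def select_long_b_genes(
    genes: pd.DataFrame, eigen_track: pd.DataFrame,
    min_length: int = 300_000, bin_size: int = 50_000,
) -> list[RegionOfInterest]:
    """Genes spanning >= ``min_length`` whose bin-length-weighted majority of
    eigenvector bins is negative (B compartment).

    ``genes``: BED-like columns chrom, start, end, name.
    """
    out = []
    covered = set(eigen_track["chrom"].unique())
    for _, g in genes.iterrows():
        if g["end"] - g["start"] < min_length:
            continue
        if g["chrom"] not in covered:
            warnings.warn(f"gene {g.get('name', '?')} on uncovered chromosome "
                          f"{g['chrom']}; skipped")
            continue
        tr = eigen_track[eigen_track["chrom"] == g["chrom"]]
        b0, b1 = g["start"] // bin_size, -(-g["end"] // bin_size)
        sel = tr[(tr["bin"] >= b0) & (tr["bin"] < b1)].dropna(subset=["score"])
        if sel.empty:
            continue
        # weight by overlap length of each bin with the gene
        ov = (np.minimum(sel["end"], g["end"]) - np.maximum(sel["start"], g["start"])).clip(lower=0)
        neg = float(ov[sel["score"] < 0].sum())
        if neg > 0.5 * float(ov.sum()):
            out.append(RegionOfInterest(str(g.get("name", f"{g['chrom']}:{g['start']}")),
                                        g["chrom"], int(g["start"]), int(g["end"]), "B"))
    return out


def per_cell_insulation_matrix(
    pairs: pd.DataFrame, chrom_lengths: dict[str, int],
    roi: RegionOfInterest, params: InsulationParams | None = None,
) -> pd.DataFrame:
    """Cells x ROI-bins matrix of single-cell insulation scores.

    Each cell's unique valid cis pairs on the ROI chromosome are binned at
    the insulation resolution; scores are z-scored over the whole
    chromosome (so cells of different depth are comparable) and then
    restricted to the ROI bin span.
    """
    p = params or InsulationParams()
    b0, b1 = roi.bin_range(p.resolution)
    chrom = roi.chrom
    lengths = {chrom: chrom_lengths[chrom]}
    sub = pairs[(pairs["chrom1"] == chrom) & (pairs["chrom2"] == chrom)]
    rows = {}
    for cell, df in sub.groupby("cell_id", sort=True):
        bm = bin_contacts(df, p.resolution, lengths)
        track = insulation_scores(bm, p, balanced=False)
        s = track["score"].to_numpy()
        rows[cell] = s[b0:b1]
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"{chrom}:{i}" for i in range(b0, b1)])
    out.index.name = "cell_id"
    return out


@dataclass
class StateClustering:
    labels: pd.Series          # per cell: "melting" | "concretion"
    linkage_method: str
    median_melting: float
    median_concretion: float
    stable: bool = True

    @property
    def melting_cells(self) -> list:
        return list(self.labels.index[self.labels == "melting"])

    @property
    def concretion_cells(self) -> list:
        return list(self.labels.index[self.labels == "concretion"])


def cluster_states(ins_matrix: pd.DataFrame, linkage_method: str = "ward") -> StateClustering:
    """Two-state clustering of cells from ROI-restricted insulation scores.

    Rows = cells, columns = ROI bins.  Missing scores are mean-imputed per
    bin, columns z-scaled, Ward-linkage hierarchical clustering cut at
    k = 2.  The cluster with the lower median (unscaled) insulation is
    labelled melting.  A cut producing an empty or singleton cluster is
    flagged unstable.
    """
    if ins_matrix.shape[0] < 4 or ins_matrix.shape[1] < 3:
        raise ValueError("need >= 4 cells and >= 3 ROI bins")
    X = ins_matrix.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.nan_to_num(col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    lk = linkage(Z, method=linkage_method)
    cut = fcluster(lk, t=2, criterion="maxclust")
    med = {c: float(np.nanmedian(ins_matrix.to_numpy(dtype=float)[cut == c]))
           for c in np.unique(cut)}
    stable = len(med) == 2 and all((cut == c).sum() > 1 for c in med)
    if not stable:
        warnings.warn("degenerate 2-cluster cut (empty or singleton cluster); "
                      "clustering marked unstable")
    if len(med) == 1:
        only = next(iter(med))
        labels = pd.Series("concretion", index=ins_matrix.index)
        return StateClustering(labels, linkage_method, np.nan, med[only], stable=False)
    melt_c = min(med, key=med.get)
    labels = pd.Series(np.where(cut == melt_c, "melting", "concretion"),
                       index=ins_matrix.index)
    conc_c = max(med, key=med.get)
    return StateClustering(labels, linkage_method, med[melt_c], med[conc_c], stable)


@dataclass(frozen=True)
class MeltingScore:
    d: float
    p_value: float
    n_melting: int            # pooled (cell, bin) sample size
    n_concretion: int

    @property
    def significant(self) -> bool:
        return self.p_value < P_SIGNIFICANT


def ks_one_sided(melt: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    """One-sided KS: D = sup_x [F_melt(x) - F_conc(x)] (melting shifted to
    lower scores puts its CDF above), p = exp(-2 D^2 mn/(m+n))."""
    melt = np.sort(melt[~np.isnan(melt)])
    conc = np.sort(conc[~np.isnan(conc)])
    m, n = len(melt), len(conc)
    if m == 0 or n == 0:
        raise ValueError("empty cluster sample")
    grid = np.concatenate([melt, conc])
    fm = np.searchsorted(melt, grid, side="right") / m
    fc = np.searchsorted(conc, grid, side="right") / n
    d = float(max(0.0, np.max(fm - fc)))
    p = float(min(1.0, np.exp(-2.0 * d * d * m * n / (m + n))))
    return d, p


def melting_score(ins_matrix: pd.DataFrame, clustering: StateClustering) -> MeltingScore:
    """KS melting statistic over all pooled (cell, bin) ROI scores."""
    melt = ins_matrix.loc[clustering.melting_cells].to_numpy(dtype=float).ravel()
    conc = ins_matrix.loc[clustering.concretion_cells].to_numpy(dtype=float).ravel()
    melt, conc = melt[~np.isnan(melt)], conc[~np.isnan(conc)]
    if melt.size == 0 or conc.size == 0:
        raise ValueError("both clusters must contribute scores")
    d, p = ks_one_sided(melt, conc)
    return MeltingScore(d, p, int(melt.size), int(conc.size))


def depth_guard(unique_valid_per_cell: pd.Series, threshold: int = 250_000) -> pd.DataFrame:
    """Cells below the reliability depth threshold.

    State clustering loses discriminative power at shallow depth; callers
    proceed but the output should carry the flag.  Returns per-cell rows
    with a ``low_depth`` flag (all cells listed, flagged ones first).
    """
    df = pd.DataFrame({
        "cell_id": unique_valid_per_cell.index,
        "unique_valid_pairs": unique_valid_per_cell.to_numpy(),
    })
    df["low_depth"] = df["unique_valid_pairs"] < threshold
    return df.sort_values(["low_depth", "cell_id"],
                          ascending=[False, True]).reset_index(drop=True)
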