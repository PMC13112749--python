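"""Cell-cycle phasing (repli-score) and ploidy calling (haploid score).

The repli-score of a cell is the pseudocounted ratio of contact
endpoints in early- vs late-replicating domains; ranking cells by it
orders them along S phase.  The haploid score is the cell's
sex-chromosome endpoint fraction divided by the diploid (XY) expectation
(L_X + L_Y) / (2 L_auto + L_X + L_Y): diploid cells score ~1, haploid
cells score higher because autosomes halve while the single sex
chromosome does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genome import AUTOSOME, MITO, SEX_X, SEX_Y, ToyGenome


@dataclass
class RepliTrack:
    """Early/late replication intervals (bp, half-open, disjoint)."""

    early: dict[str, np.ndarray]   # chrom -> (n, 2) interval array
    late: dict[str, np.ndarray]

    @classmethod
    def from_intervals(cls, early: list[tuple[str, int, int]],
                       late: list[tuple[str, int, int]]) -> "RepliTrack":
        def collect(items):
            out: dict[str, list] = {}
            for chrom, a, b in items:
                out.setdefault(chrom, []).append((a, b))
            return {c: np.array(sorted(v)) for c, v in out.items()}
        tr = cls(collect(early), collect(late))
        for chrom in set(tr.early) & set(tr.late):
            e, l = tr.early[chrom], tr.late[chrom]
            edges = np.concatenate([e, l])
            order = np.argsort(edges[:, 0])
            s = edges[order]
            if np.any(s[1:, 0] < s[:-1, 1]):
                raise ValueError(f"early/late intervals overlap on {chrom}")
        return tr

    def classify(self, chrom: str, pos_1based: np.ndarray) -> np.ndarray:
        """+1 early, -1 late, 0 neither, per endpoint (1-based positions)."""
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1
        out = np.zeros(pos0.size, dtype=np.int8)
        for sign, table in ((1, self.early), (-1, self.late)):
            iv = table.get(chrom)
            if iv is None or not len(iv):
                continue
            idx = np.searchsorted(iv[:, 0], pos0, side="right") - 1
            ok = (idx >= 0) & (pos0 < iv[np.clip(idx, 0, len(iv) - 1), 1])
            out[ok] = sign
        return out


def _endpoint_counts(pairs: pd.DataFrame, fn) -> pd.DataFrame:
    """Apply a per-endpoint classifier (chrom, pos) -> values; returns the
    long frame of (cell_id, value) over both endpoints of every pair."""
    parts = []
    for c_col, p_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
        vals = np.empty(len(pairs), dtype=np.int8)
        chroms = pairs[c_col].to_numpy()
        pos = pairs[p_col].to_numpy()
        for ch in pd.unique(chroms):
            m = chroms == ch
            vals[m] = fn(ch, pos[m])
        parts.append(pd.DataFrame({"cell_id": pairs["cell_id"], "value": vals}))
    return pd.concat(parts, ignore_index=True)


def repli_score(pairs: pd.DataFrame, track: RepliTrack) -> pd.DataFrame:
    """Per-cell early/late endpoint ratio (+1 pseudocounts) and rank.

    Each contact contributes two endpoints.  Rank 1 is the most-early
    cell.  Cells with no endpoint in either class are flagged
    uninformative.  Columns: cell_id, n_early, n_late, ratio, rank,
    uninformative.
    """
    long = _endpoint_counts(pairs, track.classify)
    g = long.groupby("cell_id")["value"]
    n_early = g.apply(lambda v: int((v == 1).sum()))
    n_late = g.apply(lambda v: int((v == -1).sum()))
    out = pd.DataFrame({"cell_id": n_early.index,
                        "n_early": n_early.to_numpy(),
                        "n_late": n_late.to_numpy()})
    out["ratio"] = (out["n_early"] + 1) / (out["n_late"] + 1)
    out["uninformative"] = (out["n_early"] + out["n_late"]) == 0
    if out["uninformative"].any():
        warnings.warn(f"{int(out['uninformative'].sum())} cells with no "
                      "endpoints in either replication class")
    out["rank"] = out["ratio"].rank(ascending=False, method="first").astype(int)
    return out.reset_index(drop=True)


def diploid_sex_fraction(genome: ToyGenome) -> float:
    """Expected sex-chromosome endpoint fraction of an XY diploid cell."""
    L = {cls: sum(c.length for c in genome.chromosomes if c.cls == cls)
         for cls in (AUTOSOME, SEX_X, SEX_Y)}
    if L[SEX_X] == 0 or L[SEX_Y] == 0:
        raise ValueError("genome does not declare sex_X and sex_Y chromosomes")
    return (L[SEX_X] + L[SEX_Y]) / (2 * L[AUTOSOME] + L[SEX_X] + L[SEX_Y])


def haploid_score(pairs: pd.DataFrame, genome: ToyGenome,
                  threshold: float = 1.5) -> pd.DataFrame:
    """Per-cell sex-chromosome content normalized to diploid expectation.

    score = f_sex / e_dip where f_sex is the endpoint fraction on sex
    chromosomes (mito excluded from the denominator) and e_dip is
    :func:`diploid_sex_fraction`.  Cells at or above ``threshold`` are
    called haploid.  Columns: cell_id, f_sex, score, ploidy_call.
    """
    e_dip = diploid_sex_fraction(genome)
    sex = set(genome.chroms_of_class(SEX_X)) | set(genome.chroms_of_class(SEX_Y))
    mito = {genome.mito_chrom}

    def classify(chrom, pos):
        if chrom in sex:
            return np.ones(len(pos), dtype=np.int8)
        if chrom in mito:
            return np.full(len(pos), -9, dtype=np.int8)   # excluded
        return np.zeros(len(pos), dtype=np.int8)

    long = _endpoint_counts(pairs, classify)
    long = long[long["value"] != -9]
    g = long.groupby("cell_id")["value"]
    n_sex = g.sum()
    n_tot = g.count()
    out = pd.DataFrame({"cell_id": n_sex.index,
                        "f_sex": (n_sex / n_tot).to_numpy(dtype=float)})
    out["score"] = out["f_sex"] / e_dip
    out["ploidy_call"] = np.where(out["score"] >= threshold, "haploid", "diploid")
    return out.reset_index(drop=True)


def group_compare_trans_cis(qc: pd.DataFrame, ploidy_calls: pd.DataFrame) -> dict:
    """Compare log2 trans/cis between haploid- and diploid-called cells.

    Returns per-group medians and a two-sided rank-sum (Mann-Whitney)
    p-value; groups smaller than 3 get statistics without a test.
    """
    df = qc.merge(ploidy_calls[["cell_id", "ploidy_call"]], on="cell_id")
    groups = {name: g["log2_trans_cis"].dropna().to_numpy()
              for name, g in df.groupby("ploidy_call")}
    if len(groups) < 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError("both groups must be non-empty")
    out = {f"median_{k}": float(np.median(v)) for k, v in groups.items()}
    out.update({f"n_{k}": int(len(v)) for k, v in groups.items()})
    a, b = (groups.get("haploid"), groups.get("diploid"))
    if a is not None and b is not None and len(a) >= 3 and len(b) >= 3:
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        out["rank_sum_statistic"] = float(stat)
        out["p_value"] = float(p)
    else:
        warnings.warn("a group has fewer than 3 cells; rank-sum test skipped")
    return out
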