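"""Insulation scores, TAD boundary calls, A/B compartment eigenvectors and
track correlations.

The insulation score of a bin is the mean contact count in "diamond"
windows spanning it (rows upstream x columns downstream, the anchor bin
excluded), z-scored per chromosome for each window size and averaged
across window sizes; boundaries are prominent local minima.  The
compartment score is the leading eigenvector of the Pearson correlation
matrix of the distance-normalized (observed/expected) cis matrix, sign-
oriented against a reference track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .matrix import BinnedMatrix


@dataclass(frozen=True)
class InsulationParams:
    resolution: int = 50_000
    min_depth: int = 200_000
    max_depth: int = 750_000
    step: int = 50_000

    @property
    def windows(self) -> list[int]:
        """Window sizes in bins."""
        for d in (self.min_depth, self.max_depth, self.step):
            if d % self.resolution:
                raise ValueError("depths must be multiples of the resolution")
        return list(range(self.min_depth // self.resolution,
                          self.max_depth // self.resolution + 1,
                          self.step // self.resolution))


def diamond_means(M: np.ndarray, w: int) -> np.ndarray:
    """Mean of M[i-w:i, i+1:i+w+1] per bin; NaN where the window is cut off
    by a chromosome edge (full-window policy)."""
    n = M.shape[0]
    out = np.full(n, np.nan)
    # summed-area table for O(n) diamonds
    S = np.zeros((n + 1, n + 1))
    S[1:, 1:] = np.nancumsum(np.nancumsum(np.nan_to_num(M), axis=0), axis=1)
    for i in range(w, n - w):
        r0, r1 = i - w, i            # rows [i-w, i-1]
        c0, c1 = i + 1, i + w + 1    # cols [i+1, i+w]
        total = S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]
        out[i] = total / (w * w)
    return out


def insulation_scores(
    bm: BinnedMatrix, params: InsulationParams | None = None,
    balanced: bool = False, chroms: list[str] | None = None,
) -> pd.DataFrame:
    """Multi-window TAD-separation score per bin.

    Per window size: diamond mean, then per-chromosome z-score; the final
    score is the mean of z-scores across window sizes.  Lower score means
    stronger boundary.  Bins where the largest window does not fit are
    masked (NaN).  Columns: chrom, bin, start, end, score.
    """
    p = params or InsulationParams()
    if bm.bin_size != p.resolution:
        raise ValueError("matrix bin size must equal the insulation resolution")
    wmax = max(p.windows)
    rows = []
    for chrom in (chroms or list(bm.chrom_lengths)):
        n = bm.chrom_nbins(chrom)
        if n < 2 * wmax + 1:
            warnings.warn(f"{chrom}: shorter than twice the largest window; masked")
            score = np.full(n, np.nan)
        else:
            M = bm.cis_dense(chrom, balanced=balanced)
            zs = []
            for w in p.windows:
                d = diamond_means(M, w)
                valid = ~np.isnan(d)
                mu, sd = d[valid].mean(), d[valid].std()
                z = (d - mu) / sd if sd > 0 else np.where(valid, 0.0, np.nan)
                zs.append(z)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge bins
                score = np.nanmean(np.vstack(zs), axis=0)
            score[: wmax] = np.nan
            score[n - wmax :] = np.nan
        rows.append(pd.DataFrame({
            "chrom": chrom, "bin": np.arange(n),
            "start": np.arange(n) * p.resolution,
            "end": np.minimum((np.arange(n) + 1) * p.resolution,
                              bm.chrom_lengths[chrom]),
            "score": score,
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class BoundaryCallParams:
    delta: float = 0.01               # minimum prominence of an insulation minimum
    threshold_comparisons: float = 0.05

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def call_boundaries(track: pd.DataFrame,
                    params: BoundaryCallParams | None = None) -> pd.DataFrame:
    """Boundaries = local insulation minima with prominence >= delta;
    minima within 2 bins of each other merge to the deeper one."""
    p = params or BoundaryCallParams()
    out = []
    for chrom, g in track.groupby("chrom", sort=False):
        s = g["score"].to_numpy()
        valid = ~np.isnan(s)
        if valid.sum() < 3:
            continue
        filled = np.where(valid, s, np.nanmax(s[valid]))
        peaks, _ = find_peaks(-filled, prominence=p.delta)
        peaks = peaks[valid[peaks]]
        # merge minima closer than 2 bins, keeping the deeper
        merged: list[int] = []
        for pk in sorted(peaks):
            if merged and pk - merged[-1] <= 2:
                if filled[pk] < filled[merged[-1]]:
                    merged[-1] = pk
            else:
                merged.append(pk)
        for pk in merged:
            row = g.iloc[pk]
            out.append({"chrom": chrom, "bin": int(row["bin"]),
                        "start": int(row["start"]), "end": int(row["end"]),
                        "score": float(row["score"])})
    return pd.DataFrame(out, columns=["chrom", "bin", "start", "end", "score"])


def leading_eigenvector(corr: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-norm eigenvector of the largest-magnitude eigenvalue."""
    vals, vecs = np.linalg.eigh(corr)
    k = int(np.argmax(np.abs(vals)))
    v = vecs[:, k]
    return v / np.linalg.norm(v), float(vals[k])


def observed_expected(M: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean (NaN-aware)."""
    n = M.shape[0]
    OE = np.full_like(M, np.nan, dtype=float)
    for d in range(n):
        diag = np.diagonal(M, offset=d)
        mu = np.nanmean(diag) if np.any(~np.isnan(diag)) else np.nan
        if not np.isfinite(mu) or mu == 0:
            continue
        idx = np.arange(n - d)
        OE[idx, idx + d] = diag / mu
        OE[idx + d, idx] = diag / mu
    return OE


def compartment_eigenvector(
    bm: BinnedMatrix, orientation: pd.DataFrame | None = None,
    balanced: bool = False, min_bins: int = 10,
) -> pd.DataFrame:
    """Per-chromosome compartment score (leading O/E-correlation eigenvector).

    ``orientation``: track with columns (chrom, bin, value) — e.g. an
    A-compartment indicator or gene density — used only to fix the sign so
    that positive scores mean A-like bins.  Masked bins come back NaN.
    Columns: chrom, bin, start, end, score.
    """
    rows = []
    for chrom in bm.chrom_lengths:
        n = bm.chrom_nbins(chrom)
        score = np.full(n, np.nan)
        M = bm.cis_dense(chrom, balanced=balanced)
        cov = np.nansum(np.nan_to_num(M), axis=1)
        keep = cov > 0
        if bm.mask is not None:
            o = bm.offsets[chrom]
            keep &= ~bm.mask[o : o + n]
        if keep.sum() < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} unmasked bins; skipped")
        else:
            sub = M[np.ix_(keep, keep)]
            OE = observed_expected(sub)
            OE = np.nan_to_num(OE, nan=1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = np.corrcoef(OE)
            corr = np.nan_to_num(corr)
            v, _ = leading_eigenvector(corr)
            if orientation is not None:
                ref = orientation[orientation["chrom"] == chrom].set_index("bin")["value"]
                ref_v = ref.reindex(np.flatnonzero(keep)).to_numpy(dtype=float)
                ok = ~np.isnan(ref_v)
                if ok.sum() >= 3 and np.corrcoef(v[ok], ref_v[ok])[0, 1] < 0:
                    v = -v
            score[keep] = v
        rows.append(pd.DataFrame({
            "chrom": chrom, "bin": np.arange(n),
            "start": np.arange(n) * bm.bin_size,
            "end": np.minimum((np.arange(n) + 1) * bm.bin_size,
                              bm.chrom_lengths[chrom]),
            "score": score,
        }))
    return pd.concat(rows, ignore_index=True)


def track_correlation(a: pd.DataFrame, b: pd.DataFrame,
                      value_a: str = "score", value_b: str = "score") -> float:
    """Pearson correlation over jointly unmasked (chrom, bin) entries."""
    m = a[["chrom", "bin", value_a]].merge(
        b[["chrom", "bin", value_b]], on=["chrom", "bin"],
        suffixes=("_a", "_b"))
    va = m[value_a + "_a"] if value_a == value_b else m[value_a]
    vb = m[value_b + "_b"] if value_a == value_b else m[value_b]
    ok = va.notna() & vb.notna()
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly unmasked bins")
    va, vb = va[ok].to_numpy(float), vb[ok].to_numpy(float)
    if va.std() == 0 or vb.std() == 0:
        warnings.warn("zero variance in a track; correlation undefined")
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])
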