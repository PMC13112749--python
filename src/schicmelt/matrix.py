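"""Sparse contact matrices: binning, ICE balancing, decay, downsampling,
library-complexity saturation fits, coverage and aggregate peak analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import curve_fit


@dataclass
class BinnedMatrix:
    """Genome-wide upper-triangle contact matrix at a fixed bin size.

    Bins are numbered globally, chromosome by chromosome; ``weights`` are
    ICE biases (balanced count = raw / (w_i * w_j)) on unmasked bins.
    """

    bin_size: int
    chrom_lengths: dict[str, int]
    mat: sp.csr_matrix = field(repr=False)      # upper triangle, i <= j
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None              # True = excluded bin
    converged: bool | None = None

    @property
    def n_bins(self) -> int:
        return self.mat.shape[0]

    @property
    def offsets(self) -> dict[str, int]:
        off, out = 0, {}
        for c, L in self.chrom_lengths.items():
            out[c] = off
            off += -(-L // self.bin_size)
        return out

    def chrom_nbins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)

    def bin_of(self, chrom: str, pos_1based) -> np.ndarray:
        return self.offsets[chrom] + (np.asarray(pos_1based, dtype=np.int64) - 1) // self.bin_size

    def symmetric(self) -> sp.csr_matrix:
        u = self.mat.tocsr()
        return u + u.T - sp.diags(u.diagonal())

    def cis_dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Dense symmetric cis block of one chromosome."""
        o, n = self.offsets[chrom], self.chrom_nbins(chrom)
        block = self.symmetric()[o : o + n, o : o + n].toarray().astype(float)
        if balanced:
            if self.weights is None:
                raise ValueError("matrix is not balanced; call ice_balance first")
            w = self.weights[o : o + n]
            with np.errstate(invalid="ignore", divide="ignore"):
                block = block / np.outer(w, w)
            block[~np.isfinite(block)] = np.nan
        return block

    def total(self) -> float:
        return float(self.mat.sum())

    def coarsen(self, factor: int) -> "BinnedMatrix":
        """Aggregate to a bin size ``factor`` times larger (per chromosome)."""
        coarse_size = self.bin_size * factor
        coarse_lengths = dict(self.chrom_lengths)
        fine_off = self.offsets
        # map each fine global bin to its coarse global bin
        mapping = np.empty(self.n_bins, dtype=np.int64)
        coff = 0
        for c, L in self.chrom_lengths.items():
            nf = self.chrom_nbins(c)
            mapping[fine_off[c] : fine_off[c] + nf] = coff + np.arange(nf) // factor
            coff += -(-L // coarse_size)
        coo = self.mat.tocoo()
        i, j = mapping[coo.row], mapping[coo.col]
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        m = sp.coo_matrix((coo.data, (lo, hi)), shape=(coff, coff)).tocsr()
        m.sum_duplicates()
        return BinnedMatrix(coarse_size, coarse_lengths, m)


def bin_contacts(pairs: pd.DataFrame, bin_size: int,
                 chrom_lengths: dict[str, int]) -> BinnedMatrix:
    """Bin contact pairs; each pair increments exactly one (i <= j) cell, so
    total matrix mass equals the number of input pairs."""
    if bin_size < 1000:
        raise ValueError("bin size must be >= 1 kb")
    off, nbins = {}, 0
    for c, L in chrom_lengths.items():
        off[c] = nbins
        nbins += -(-L // bin_size)
    for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
        for c in pairs[col_c].unique():
            if c not in chrom_lengths:
                raise ValueError(f"chromosome {c} absent from chrom_lengths")
            p = pairs.loc[pairs[col_c] == c, col_p]
            if (p < 1).any() or (p > chrom_lengths[c]).any():
                raise ValueError(f"position beyond bounds of {c}")
    b1 = np.empty(len(pairs), dtype=np.int64)
    b2 = np.empty(len(pairs), dtype=np.int64)
    for col_c, col_p, out in (("chrom1", "pos1", b1), ("chrom2", "pos2", b2)):
        chroms = pairs[col_c].to_numpy()
        pos = pairs[col_p].to_numpy(dtype=np.int64)
        for c in pd.unique(chroms):
            m = chroms == c
            out[m] = off[c] + (pos[m] - 1) // bin_size
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    m = sp.coo_matrix((np.ones(len(pairs)), (lo, hi)), shape=(nbins, nbins)).tocsr()
    m.sum_duplicates()
    return BinnedMatrix(bin_size, dict(chrom_lengths), m)


def ice_balance(bm: BinnedMatrix, max_iter: int = 200, tol: float = 1e-5,
                mask_percentile: float = 2.0) -> np.ndarray:
    """Iterative correction: equalize bin visibility.

    Masks zero-coverage bins plus the lowest ``mask_percentile`` percent of
    nonzero bins, then multiplicatively updates biases until the
    coefficient of variation of balanced row sums drops below ``tol``.
    Sets ``bm.weights``/``bm.mask``/``bm.converged`` and returns weights.
    """
    sym = bm.symmetric()
    marg = np.asarray(sym.sum(axis=1)).ravel()
    mask = marg == 0
    nz = marg[~mask]
    if nz.size and mask_percentile > 0:
        cut = np.percentile(nz, mask_percentile)
        if cut < nz.max():   # never mask a fully uniform marginal profile
            mask |= (marg > 0) & (marg <= cut)
    w = np.ones(bm.n_bins)
    keep = ~mask
    sym = sym.tocsr()
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            inv = np.where(keep, 1.0 / w, 0.0)
        s = (sym @ inv) * inv            # balanced row sums
        sk = s[keep]
        if sk.size == 0:
            break
        mean = sk.mean()
        if mean == 0:
            break
        cv = sk.std() / mean
        if cv < tol:
            converged = True
            break
        w[keep] *= sk / mean
    bm.weights = np.where(keep, w, np.nan)
    bm.mask = mask
    bm.converged = converged
    if not converged:
        warnings.warn("ICE did not converge within max_iter; last weights kept")
    return bm.weights


def balanced_rowsum_cv(bm: BinnedMatrix) -> float:
    """Direct recomputation of the unmasked balanced row-sum CV."""
    if bm.weights is None:
        raise ValueError("balance first")
    keep = ~bm.mask
    inv = np.where(keep, 1.0 / bm.weights, 0.0)
    s = (bm.symmetric() @ inv) * inv
    sk = s[keep]
    return float(sk.std() / sk.mean())


def distance_decay(pairs: pd.DataFrame, bins_per_decade: int = 8,
                   min_dist: float = 1_000.0) -> pd.DataFrame:
    """Cis contact probability vs genomic separation, log-spaced bins.

    Returns columns lo, hi, center, prob; prob sums to 1 over cis pairs.
    """
    cis = pairs[pairs["chrom1"] == pairs["chrom2"]]
    d = np.abs(cis["pos2"].to_numpy() - cis["pos1"].to_numpy()).astype(float)
    d = d[d >= min_dist]
    if d.size == 0:
        warnings.warn("no cis pairs at or beyond min_dist; empty decay curve")
        return pd.DataFrame(columns=["lo", "hi", "center", "prob"])
    top = np.ceil(np.log10(d.max()) * bins_per_decade) / bins_per_decade
    edges = 10 ** np.arange(np.log10(min_dist), top + 1.0 / bins_per_decade,
                            1.0 / bins_per_decade)
    hist, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({
        "lo": edges[:-1], "hi": edges[1:],
        "center": np.sqrt(edges[:-1] * edges[1:]),
        "prob": hist / hist.sum(),
    })


def decay_slope(curve: pd.DataFrame, fit_range: tuple[float, float] = (2e3, 1e6)) -> float:
    """Log-log slope of the decay *density* (probability / bin width)."""
    c = curve[(curve["center"] >= fit_range[0]) & (curve["center"] <= fit_range[1])]
    c = c[c["prob"] > 0]
    dens = c["prob"] / (c["hi"] - c["lo"])
    return float(np.polyfit(np.log10(c["center"]), np.log10(dens), 1)[0])


def downsample_pairs(pairs: pd.DataFrame, n: int, rng_seed: int = 0) -> pd.DataFrame:
    """Uniform sample of ``n`` pairs without replacement (original order kept)."""
    if n > len(pairs):
        raise ValueError(f"requested {n} pairs but only {len(pairs)} available")
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(len(pairs), size=n, replace=False))
    return pairs.iloc[idx].reset_index(drop=True)


def downsample_per_cell(pairs: pd.DataFrame, n: int, rng_seed: int = 0) -> pd.DataFrame:
    """Downsample every cell to exactly ``n`` pairs (cells with fewer are
    dropped), equalizing depth before per-cell comparisons such as state
    clustering."""
    rng = np.random.default_rng(rng_seed)
    kept = []
    for cell, df in pairs.groupby("cell_id", sort=True):
        if len(df) < n:
            continue
        kept.append(downsample_pairs(df, n, int(rng.integers(0, 2**31))))
    if not kept:
        raise ValueError(f"no cell reaches {n} pairs")
    return pd.concat(kept, ignore_index=True)


@dataclass(frozen=True)
class SaturationFit:
    """Hyperbolic saturation model Y = Bmax * X / (Kd + X): Bmax is the
    asymptotic number of unique valid pairs (the saturation point), Kd the
    depth at half saturation."""

    bmax: float
    kd: float
    x: np.ndarray
    y: np.ndarray
    residuals: np.ndarray

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return self.bmax * x / (self.kd + x)


def saturation_fit(depths, unique_pairs) -> SaturationFit:
    """Least-squares fit of the saturation curve (linear space, positivity
    constrained; initialized at Bmax = 2*max(Y), Kd = median(X))."""
    x = np.asarray(depths, float)
    y = np.asarray(unique_pairs, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct depths")
    if np.all(y == 0):
        raise ValueError("degenerate data: all unique-pair counts are zero")
    p0 = (2.0 * y.max(), float(np.median(x)))
    popt, _ = curve_fit(lambda xx, b, k: b * xx / (k + xx), x, y, p0=p0,
                        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20_000)
    bmax, kd = float(popt[0]), float(popt[1])
    resid = y - bmax * x / (kd + x)
    return SaturationFit(bmax, kd, x, y, resid)


DEPTH_LADDER = (15_625, 31_250, 62_500, 125_000, 250_000,
                500_000, 1_000_000, 2_000_000, 4_000_000)
"""Standard read-downsampling ladder for saturation analysis."""


def coverage_fraction(
    pairs_by_cell: dict[str, pd.DataFrame],
    bin_sizes, depth_thresholds,
    chrom_lengths: dict[str, int],
    exclude_chroms: set[str] = frozenset(),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Fraction of genomic bins touched by >= 1 contact endpoint after
    downsampling each cell to each depth threshold.

    Only cells with at least the threshold number of pairs enter a row;
    endpoints on ``exclude_chroms`` (e.g. the mitochondrial contig) are
    ignored and those bins are excluded from the denominator.
    """
    chroms = {c: L for c, L in chrom_lengths.items() if c not in exclude_chroms}
    rows = []
    for cell, df in pairs_by_cell.items():
        for thr in depth_thresholds:
            if len(df) < thr:
                continue
            sub = downsample_pairs(df, int(thr), rng_seed)
            for bs in bin_sizes:
                nbins, covered = 0, set()
                off = {}
                for c, L in chroms.items():
                    off[c] = nbins
                    nbins += -(-L // bs)
                for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
                    m = sub[col_c].isin(chroms)
                    g = sub.loc[m]
                    for c in g[col_c].unique():
                        p = g.loc[g[col_c] == c, col_p].to_numpy(dtype=np.int64)
                        covered.update((off[c] + (p - 1) // bs).tolist())
                rows.append({"cell_id": cell, "bin_size": int(bs),
                             "threshold": int(thr),
                             "fraction": len(covered) / nbins})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class APAResult:
    window: np.ndarray          # (2k+1, 2k+1) mean window, centered on loops
    enrichment: float
    n_loops: int
    n_excluded: int


def apa(bm: BinnedMatrix, loops: pd.DataFrame, half_window: int = 10,
        corner: int = 3, balanced: bool = True) -> APAResult:
    """Aggregate peak analysis: mean (2k+1)^2 window over loop pixels.

    Enrichment = center value / mean of the c x c maximum-distance corner
    (the "lower left" of the conventional APA rendering).  Loops closer
    than k + c bins to a matrix edge or to the diagonal are excluded.
    """
    k, c = half_window, corner
    acc = np.zeros((2 * k + 1, 2 * k + 1))
    n_used = n_excluded = 0
    dense_cache: dict[str, np.ndarray] = {}
    for _, row in loops.iterrows():
        ch = row["chrom1"]
        if row.get("chrom2", ch) != ch:
            n_excluded += 1
            continue
        if ch not in dense_cache:
            dense_cache[ch] = bm.cis_dense(ch, balanced=balanced and bm.weights is not None)
        M = dense_cache[ch]
        o = bm.offsets[ch]
        bi = int(bm.bin_of(ch, (row["start1"] + row["end1"]) // 2)) - o
        bj = int(bm.bin_of(ch, (row["start2"] + row["end2"]) // 2)) - o
        bi, bj = min(bi, bj), max(bi, bj)
        n = M.shape[0]
        if bi - k < 0 or bj + k >= n or (bj - bi) <= k + c:
            n_excluded += 1
            continue
        win = M[bi - k : bi + k + 1, bj - k : bj + k + 1]
        if np.isnan(win).any():
            n_excluded += 1
            continue
        acc += win
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no eligible loops (excluded {n_excluded}: too close "
                         "to an edge/diagonal, trans, or masked bins)")
    mean_win = acc / n_used
    corner_block = mean_win[:c, -c:]   # di=-k, dj=+k: the max-distance corner
    enrichment = float(mean_win[k, k] / corner_block.mean())
    return APAResult(mean_win, enrichment, n_used, n_excluded)
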