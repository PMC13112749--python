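"""Barcode-rank cell calling, species assignment and collision estimation.

Valid cells are found from the barcode rank plot (barcodes sorted by
descending unique valid pairs) via two knee points: knee2 separates real
cells from the background-barcode cloud, knee1 (searched above knee2)
separates a doublet-prone high-count plateau when one exists.  In a
two-species barnyard design, called cells whose contacts do not reach the
species-purity threshold (default 89%) on either genome are
cross-species doublets; their share of valid cells is the collision rate.

Knee rule: each knee is the point of maximum distance between the
(linear rank, normalized log10 count) curve and its end-to-end chord,
accepted only when the local drop across the candidate exceeds the mean
chord slope by a contrast factor — a curve without a genuine cliff
(log-linear, or a pure power law) therefore yields an explicit no-knee
result instead of an arbitrary point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABELS = ("doublet_prone", "valid", "background")


def rank_barcodes(counts: pd.Series | dict) -> pd.DataFrame:
    """Sort barcodes by descending unique valid pairs.

    Stable: ties are broken by lexicographic barcode order, so output is
    deterministic across runs.  Columns: barcode, count, rank.
    """
    s = pd.Series(counts, name="count")
    if len(s) < 3:
        raise ValueError("need at least 3 barcodes")
    df = s.rename_axis("barcode").reset_index()
    df = df.sort_values(["count", "barcode"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class KneeCall:
    knee1: int                      # rank; 0 when no doublet plateau detected
    knee2: int                      # rank; 0 when no knee found at all
    labels: pd.DataFrame = field(repr=False)  # barcode, count, rank, label
    found: bool = True

    @property
    def n_valid(self) -> int:
        return int((self.labels["label"] == "valid").sum())


def _knee_candidate(counts: np.ndarray, sensitivity: float, contrast: float):
    """Find a cliff on the (linear rank, normalized log10 count) curve.

    A rank qualifies as a cliff base when the count gap into it exceeds
    ``contrast * sensitivity`` times the local median gap (scale-free, so
    smooth curves — log-linear or pure power law — never qualify) and its
    distance below the end-to-end chord exceeds ``0.05 * sensitivity``.
    Among qualifying bases the one of maximum chord distance wins.
    Returns the 1-based rank of the last point *above* the cliff, or None.
    """
    n = len(counts)
    if n < 10:
        return None
    y = np.log10(np.maximum(counts.astype(float), 1.0))
    span = y.max() - y.min()
    if span < 1e-12:
        return None
    yn = (y - y.min()) / span
    xn = np.arange(n) / (n - 1)
    d = 1.0 - xn - yn           # distance below the chord (convex profile)
    gap = np.zeros(n)
    gap[1:] = y[:-1] - y[1:]    # drop into each rank
    # a cliff concentrates a dominant share of the dynamic range in one rank
    cand = np.flatnonzero((gap >= 0.1 * span * sensitivity)
                          & (d >= 0.05 * sensitivity))
    cand = cand[(cand > 0) & (cand < n - 1)]
    floor = 0.1 * span / (n - 1)          # guards tied-count plateaus
    qual = []
    for i in cand:
        # contrast against the local gap scale on a log-spaced window, so
        # self-similar curves (pure power laws) never qualify anywhere
        lo, hi = max(1, i // 2), min(n, 2 * i + 2)
        med = float(np.median(gap[lo:hi]))
        if gap[i] >= contrast * sensitivity * max(med, floor):
            qual.append(i)
    if not qual:
        return None
    qual = np.asarray(qual)
    k = int(qual[np.argmax(d[qual])])
    return k  # 0-based cliff base == 1-based rank of the last point above it


def find_knees(curve: pd.DataFrame, sensitivity: float = 1.0,
               contrast: float = 5.0) -> KneeCall:
    """Two-knee cell calling on a barcode rank curve.

    knee2 is found on the full curve; knee1 on the sub-curve of ranks
    <= knee2.  Barcodes with rank in (knee1, knee2] are valid cells,
    ranks <= knee1 doublet-prone, ranks > knee2 background.  A monotone
    featureless curve yields ``found=False`` with every barcode labelled
    background.
    """
    if len(curve) < 10:
        raise ValueError("curve too short for knee detection (need >= 10)")
    counts = curve["count"].to_numpy()
    labels = curve.copy()
    k2 = _knee_candidate(counts, sensitivity, contrast)
    if k2 is None:
        warnings.warn("no knee found: featureless rank curve; all barcodes "
                      "labelled background")
        labels["label"] = "background"
        return KneeCall(0, 0, labels, found=False)
    k1 = _knee_candidate(counts[:k2], sensitivity, contrast) or 0
    lab = np.full(len(curve), "background", dtype=object)
    r = labels["rank"].to_numpy()
    lab[(r > k1) & (r <= k2)] = "valid"
    lab[r <= k1] = "doublet_prone"
    labels["label"] = lab
    return KneeCall(int(k1), int(k2), labels)


@dataclass
class SpeciesCall:
    calls: pd.DataFrame     # barcode, fraction per species, label
    threshold: float


def assign_species(
    species_counts: pd.DataFrame, threshold: float = 0.89
) -> SpeciesCall:
    """Label each valid cell by genome-of-origin purity.

    ``species_counts``: one row per cell, one column per species with
    unique-valid-pair counts.  A cell is assigned to a species when at
    least ``threshold`` (inclusive) of its unique valid pairs map to that
    genome; otherwise it is a cross-species doublet.
    """
    if species_counts.shape[1] != 2:
        raise ValueError("exactly two species are required")
    totals = species_counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cells with zero unique valid pairs excluded")
    sc = species_counts.loc[~empty]
    frac = sc.div(sc.sum(axis=1), axis=0)
    label = np.full(len(frac), "doublet", dtype=object)
    for sp in frac.columns:
        label[(frac[sp] >= threshold).to_numpy()] = sp
    out = frac.copy()
    out.columns = [f"frac_{c}" for c in frac.columns]
    out["label"] = label
    return SpeciesCall(out.reset_index(), threshold)


@dataclass(frozen=True)
class CollisionEstimate:
    n_valid_cells: int
    n_doublets: int
    rate: float


def collision_rate(species_call: SpeciesCall) -> CollisionEstimate:
    """Cross-species doublets over valid cells (doublets included in the
    denominator)."""
    n = len(species_call.calls)
    if n == 0:
        raise ValueError("no valid cells")
    k = int((species_call.calls["label"] == "doublet").sum())
    return CollisionEstimate(n, k, k / n)
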