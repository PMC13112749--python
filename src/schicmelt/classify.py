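"""Restriction-fragment assignment, pair classification, dedup, per-cell QC.

Classification follows the HiC-Pro conventions: read ends are assigned to
restriction fragments by their 5' mapped position; pairs on the same
fragment are ligation artifacts (dangling end / self-circle), inward pairs
on adjacent fragments are religations, and everything else that maps well
is a valid contact. The valid-pair ratio (valid pairs before
deduplication over reported pairs) is the library-efficiency benchmark.

Coordinates: pair tables carry 1-based positions (pairs-format
convention); fragment intervals are 0-based half-open internally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import MOTIF, ToyGenome

CATEGORIES = ("valid", "dangling_end", "self_circle", "religation", "dumped")

PAIR_COLUMNS = [
    "read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
    "mapq1", "mapq2", "cell_id",
]


class FragmentMap:
    """Per-chromosome sorted cut positions with global fragment indexing.

    Fragments tile each chromosome exactly: ``k`` cut sites produce
    ``k + 1`` half-open fragments ``[0, c1), [c1, c2), ..., [ck, L)``.
    """

    def __init__(self, cuts: dict[str, np.ndarray], lengths: dict[str, int]):
        self.cuts = {c: np.asarray(v, dtype=np.int64) for c, v in cuts.items()}
        self.lengths = dict(lengths)
        self.offsets: dict[str, int] = {}
        off = 0
        for chrom in self.cuts:
            self.offsets[chrom] = off
            off += len(self.cuts[chrom]) + 1
        self.n_fragments = off

    def lookup(self, chrom: str, pos_1based: np.ndarray | int) -> np.ndarray:
        """Global fragment index covering each 1-based position."""
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1
        length = self.lengths[chrom]
        if np.any(pos0 < 0) or np.any(pos0 >= length):
            raise ValueError(f"position outside chromosome {chrom} (length {length})")
        local = np.searchsorted(self.cuts[chrom], pos0, side="right")
        return self.offsets[chrom] + local

    def fragment_bounds(self, chrom: str) -> np.ndarray:
        """(n_frag + 1) breakpoints: 0, cuts..., length."""
        return np.concatenate([[0], self.cuts[chrom], [self.lengths[chrom]]])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.cuts:
                bounds = self.fragment_bounds(chrom)
                for i in range(len(bounds) - 1):
                    fh.write(f"{chrom}\t{bounds[i]}\t{bounds[i + 1]}\tfrag_{self.offsets[chrom] + i}\n")


def digest_genome(source, motif: str = MOTIF, cut_offset: int = 0) -> FragmentMap:
    """Build a FragmentMap from a ToyGenome or a FASTA file.

    For sequence input every forward-strand occurrence of ``motif`` is
    located (GATC is its own reverse complement, so one strand suffices)
    and the cut placed at ``occurrence_start + cut_offset`` (default 0,
    i.e. DpnII-style ^GATC).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not (0 <= cut_offset <= len(motif)):
        raise ValueError("cut_offset must lie within the motif")
    if isinstance(source, ToyGenome):
        lengths = {c.name: c.length for c in source.chromosomes}
        cuts = {c: s + cut_offset for c, s in source.cut_sites.items()}
        cuts = {c: s[(s > 0) & (s < lengths[c])] for c, s in cuts.items()}
        return FragmentMap(cuts, lengths)
    # FASTA path
    from Bio import SeqIO

    cuts, lengths = {}, {}
    motif_u = motif.upper()
    for rec in SeqIO.parse(str(source), "fasta"):
        seq = str(rec.seq).upper()
        sites = []
        start = seq.find(motif_u)
        while start != -1:
            cut = start + cut_offset
            if 0 < cut < len(seq):
                sites.append(cut)
            start = seq.find(motif_u, start + 1)
        cuts[rec.id] = np.asarray(sites, dtype=np.int64)
        lengths[rec.id] = len(seq)
    return FragmentMap(cuts, lengths)


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Store mates in canonical order: (chrom1, pos1) <= (chrom2, pos2)."""
    out = pairs.copy()
    c1, c2 = out["chrom1"].to_numpy(), out["chrom2"].to_numpy()
    p1, p2 = out["pos1"].to_numpy(), out["pos2"].to_numpy()
    swap = (c1 > c2) | ((c1 == c2) & (p1 > p2))
    if swap.any():
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"),
                     ("strand1", "strand2"), ("mapq1", "mapq2")):
            if a in out.columns:
                va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
                va[swap], vb[swap] = vb[swap], va[swap].copy()
                out[a], out[b] = va, vb
    return out


def classify_pairs(
    pairs: pd.DataFrame, fragmap: FragmentMap, min_mapq: int = 10
) -> pd.DataFrame:
    """Assign fragments and the HiC-Pro category to each pair.

    Rule table on canonically ordered mates:

    a. either mapq below ``min_mapq``      -> dumped (not reported)
    b. different chromosomes               -> valid (trans)
    c. same fragment, strands (+,-)        -> dangling_end
    d. same fragment, strands (-,+)        -> self_circle
    e. same fragment, same strand          -> dumped
    f. adjacent fragments, strands (+,-)   -> religation
    g. otherwise                           -> valid (cis)
    """
    out = canonicalize_pairs(pairs)
    n = len(out)
    frag1 = np.empty(n, dtype=np.int64)
    frag2 = np.empty(n, dtype=np.int64)
    for chrom in out["chrom1"].unique():
        m = (out["chrom1"] == chrom).to_numpy()
        frag1[m] = fragmap.lookup(chrom, out.loc[m, "pos1"].to_numpy())
    for chrom in out["chrom2"].unique():
        m = (out["chrom2"] == chrom).to_numpy()
        frag2[m] = fragmap.lookup(chrom, out.loc[m, "pos2"].to_numpy())
    out["fragment1"], out["fragment2"] = frag1, frag2

    s1 = out["strand1"].to_numpy()
    s2 = out["strand2"].to_numpy()
    same_chrom = (out["chrom1"] == out["chrom2"]).to_numpy()
    same_frag = (frag1 == frag2) & same_chrom
    adjacent = (np.abs(frag2 - frag1) == 1) & same_chrom
    inward = (s1 == "+") & (s2 == "-")
    outward = (s1 == "-") & (s2 == "+")

    cat = np.full(n, "valid", dtype=object)
    cat[same_frag & inward] = "dangling_end"
    cat[same_frag & outward] = "self_circle"
    cat[same_frag & (s1 == s2)] = "dumped"
    cat[adjacent & inward] = "religation"

    if "mapq1" in out.columns:
        mapq_ok = (out["mapq1"].to_numpy() >= min_mapq) & (out["mapq2"].to_numpy() >= min_mapq)
    else:
        mapq_ok = np.ones(n, dtype=bool)
    cat[~mapq_ok] = "dumped"
    out["category"] = cat
    out["reported"] = mapq_ok
    return out


def deduplicate(classified: pd.DataFrame) -> pd.DataFrame:
    """Flag exact coordinate duplicates within each cell (first kept).

    A pair is a duplicate iff an earlier pair of the same cell has an
    identical (chrom1, pos1, strand1, chrom2, pos2, strand2) tuple.
    Order-stable: the input row order is preserved.
    """
    out = classified.copy()
    key = ["cell_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    out["duplicate"] = out.duplicated(subset=key, keep="first")
    return out


def cell_qc(
    classified: pd.DataFrame,
    genome: ToyGenome | None = None,
    mito_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics.

    ``valid_pair_ratio`` uses valid pairs *before* deduplication over
    reported (mapq-passing) pairs; ``dup_rate`` is the duplicated share of
    valid pairs; cis/trans counts use unique valid pairs. When a genome
    (or explicit mito chromosome set) is given, ``fp_rate`` is the
    fraction of unique valid pairs with exactly one end on the
    mitochondrial contig.
    """
    df = classified
    if "duplicate" not in df.columns:
        df = deduplicate(df)
    if mito_chroms is None and genome is not None:
        mito_chroms = {genome.mito_chrom}

    valid = df["category"] == "valid"
    uniq_valid = valid & ~df["duplicate"]
    cis = uniq_valid & (df["chrom1"] == df["chrom2"])
    trans = uniq_valid & (df["chrom1"] != df["chrom2"])
    agg = pd.DataFrame({
        "cell_id": df["cell_id"],
        "total": 1,
        "reported": df["reported"].astype(int),
        "valid": valid.astype(int),
        "unique_valid": uniq_valid.astype(int),
        "cis": cis.astype(int),
        "trans": trans.astype(int),
    })
    if mito_chroms:
        mito1 = df["chrom1"].isin(mito_chroms)
        mito2 = df["chrom2"].isin(mito_chroms)
        agg["mito_fp"] = (uniq_valid & (mito1 ^ mito2)).astype(int)
    g = agg.groupby("cell_id", sort=True).sum()

    qc = pd.DataFrame(index=g.index)
    qc["total_pairs"] = g["total"]
    qc["reported_pairs"] = g["reported"]
    qc["valid_pairs"] = g["valid"]
    qc["unique_valid_pairs"] = g["unique_valid"]
    with np.errstate(invalid="ignore", divide="ignore"):
        qc["valid_pair_ratio"] = np.where(
            g["reported"] > 0, g["valid"] / g["reported"], np.nan
        )
        qc["reported_pair_ratio"] = np.where(
            g["total"] > 0, g["reported"] / g["total"], np.nan
        )
        qc["dup_rate"] = np.where(
            g["valid"] > 0, 1.0 - g["unique_valid"] / g["valid"], np.nan
        )
    qc["cis"] = g["cis"]
    qc["trans"] = g["trans"]
    qc["log2_cis_trans"] = np.log2((g["cis"] + 1) / (g["trans"] + 1))
    qc["log2_trans_cis"] = -qc["log2_cis_trans"]
    if "mito_fp" in g.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            qc["fp_rate"] = np.where(
                g["unique_valid"] > 0, g["mito_fp"] / g["unique_valid"], np.nan
            )
    return qc.reset_index()


def false_positive_rate(
    classified: pd.DataFrame, genome: ToyGenome
) -> pd.DataFrame:
    """Mito-nuclear contact rate per cell: unique valid pairs with exactly
    one end on the mitochondrial contig (cis-mito pairs do not count)."""
    mito = {genome.mito_chrom}
    if not mito:
        raise ValueError("genome declares no mito chromosome")
    qc = cell_qc(classified, mito_chroms=mito)
    return qc[["cell_id", "fp_rate"]]
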