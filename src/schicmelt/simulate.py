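"""Planted-truth simulator for barcode-tagged single-cell Hi-C contact pairs.

Emulates a two-species barnyard library: real cells (with a melting or
concretion chromatin state, a ploidy class and a cell-cycle phase),
cross-species doublets, low-count background barcodes, ligation artifacts
(dangling ends, self-circles, religations, same-fragment dumped pairs),
PCR duplicates and mito-nuclear false positives.  Every barcode and every
pair carries ground truth so downstream stages can be tested as
parameter-recovery problems.

Contact geometry: cis distances follow a truncated power law
``p(s) ~ s^-alpha``; intra-TAD and same-compartment contacts are
up-weighted by rejection; cell-cycle phase tilts both the decay exponent
and the early/late replication-domain occupancy.  Cells in the melting
state lose short-range contact density inside the designated region of
interest (their TAD boundaries there are removed), cells in the
concretion state gain dense boundaries there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FragmentMap, canonicalize_pairs, digest_genome
from .genome import AUTOSOME, MITO, SEX_X, SEX_Y, ToyGenome, default_genomes

STATES = ("melting", "concretion")
PLOIDIES = ("diploid", "haploid_X", "haploid_Y")


@dataclass(frozen=True)
class ArtifactFractions:
    """Per-pair probabilities of each planted artifact category.

    The remainder (1 - sum) is the valid fraction; defaults plant a 50%
    valid share, the efficiency regime of an enriched single-cell library.
    """

    dangling_end: float = 0.18
    self_circle: float = 0.08
    religation: float = 0.12
    dumped: float = 0.12

    @property
    def valid(self) -> float:
        return 1.0 - (self.dangling_end + self.self_circle + self.religation + self.dumped)

    def validate(self) -> None:
        parts = (self.dangling_end, self.self_circle, self.religation, self.dumped)
        if any(not 0 <= p <= 1 for p in parts) or self.valid < 0:
            raise ValueError("artifact fractions must lie in [0,1] and sum to <= 1")


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_cells`.

    Depths are desk-scale: the default 6,800 pairs/cell on the 41 Mb toy
    genome matches the per-bp contact density of 500k pairs/cell on a
    3 Gb genome.
    """

    n_cells: dict[str, int] = field(default_factory=lambda: {"alpha": 200, "beta": 200})
    doublet_rate: float = 0.0          # probability of a cross-species doublet barcode
    n_background_barcodes: int = 0
    duplicate_rate: float = 0.15
    artifact_fractions: ArtifactFractions = field(default_factory=ArtifactFractions)
    mito_fp_rate: float = 0.01
    trans_rate: float = 0.2
    decay_exponent: float = 1.0
    min_distance: float = 1_000.0       # bp, lower truncation of the cis decay

    mean_pairs_per_cell: float = 6_800.0
    log10_depth_sd: float = 0.2         # lognormal spread of per-cell depth
    background_mean_pairs: float = 25.0

    # structure
    tad_spacing: float = 1_000_000.0    # boundary grid outside the ROI
    tad_weight: float = 3.0             # intra-TAD acceptance up-weight
    compartment_block: float = 2_500_000.0
    compartment_weight: float = 3.0     # same-compartment up-weight
    melting_roi: tuple[str, int, int] = ("chrA1", 5_000_000, 10_000_000)
    concretion_spacing: float = 500_000.0  # extra ROI boundaries in the concretion state
    melt_short_range: float = 1_000_000.0
    melt_suppression: float = 8.0       # sub-Mb rejection factor in melted ROI
    melting_fraction: float = 0.3

    # phasing
    repli_block: float = 2_000_000.0
    repli_offset: float = 1_000_000.0
    repli_bias: float = 0.4             # strength of the early/late phase tilt
    phase_decay_shift: float = 0.3      # alpha modulation across the cycle
    ploidy_fractions: dict[str, float] = field(default_factory=lambda: {"diploid": 1.0})
    haploid_trans_multiplier: float = 2.0

    rng_seed: int = 0

    def validate(self) -> None:
        self.artifact_fractions.validate()
        for name, v in (("doublet_rate", self.doublet_rate),
                        ("duplicate_rate", self.duplicate_rate),
                        ("mito_fp_rate", self.mito_fp_rate),
                        ("trans_rate", self.trans_rate),
                        ("melting_fraction", self.melting_fraction)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if abs(sum(self.ploidy_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("ploidy_fractions must sum to 1")
        if any(p not in PLOIDIES for p in self.ploidy_fractions):
            raise ValueError(f"ploidy must be one of {PLOIDIES}")


@dataclass(frozen=True)
class SimCellProfile:
    barcode: tuple[int, int]
    cell_id: str
    species_tag: str
    state: str
    ploidy: str
    phase: float
    target_pair_count: int


@dataclass
class Structure:
    """Planted genome annotation shared by simulation and recovery tests."""

    boundaries: dict[str, dict[str, np.ndarray]]   # state -> chrom -> positions
    compartment_block: float
    repli_block: float
    repli_offset: float
    roi: tuple[str, int, int]

    def compartment_label(self, chrom: str, pos) -> np.ndarray:
        """+1 for A blocks, -1 for B blocks (alternating, A first)."""
        block = (np.asarray(pos) // self.compartment_block).astype(np.int64)
        return np.where(block % 2 == 0, 1, -1)

    def is_early(self, chrom: str, pos) -> np.ndarray:
        block = ((np.asarray(pos) + self.repli_offset) // self.repli_block).astype(np.int64)
        return block % 2 == 0

    def repli_intervals(self, genome: ToyGenome, which: str) -> list[tuple[str, int, int]]:
        """Early or late replication intervals, half-open bp."""
        want_early = which == "early"
        out = []
        for c in genome.chromosomes:
            if c.cls == MITO:
                continue
            edges = np.arange(-self.repli_offset, c.length + self.repli_block, self.repli_block)
            for k, lo in enumerate(edges[:-1]):
                early = k % 2 == 0
                if early == want_early:
                    a, b = max(0, int(lo)), min(c.length, int(edges[k + 1]))
                    if a < b:
                        out.append((c.name, a, b))
        return out


def default_structure(genomes: dict[str, ToyGenome], cfg: SimConfig) -> Structure:
    """Boundary grids per state; the two states differ only inside the ROI."""
    roi_chrom, roi_start, roi_end = cfg.melting_roi
    boundaries: dict[str, dict[str, np.ndarray]] = {s: {} for s in STATES}
    for g in genomes.values():
        for c in g.chromosomes:
            if c.cls == MITO:
                continue
            base = np.arange(cfg.tad_spacing, c.length, cfg.tad_spacing)
            for state in STATES:
                b = base
                if c.name == roi_chrom:
                    inside = (b >= roi_start) & (b < roi_end)
                    if state == "melting":
                        b = b[~inside]
                    else:
                        dense = np.arange(roi_start, roi_end + 1, cfg.concretion_spacing)
                        b = np.unique(np.concatenate([b[~inside], dense]))
                        b = b[(b > 0) & (b < c.length)]
                boundaries[state][c.name] = b.astype(np.int64)
    return Structure(boundaries, cfg.compartment_block, cfg.repli_block,
                     cfg.repli_offset, cfg.melting_roi)


@dataclass
class SimResult:
    pairs: pd.DataFrame       # canonical pair table + true_category ground truth
    truth: pd.DataFrame       # per-barcode planted truth
    structure: Structure
    genomes: dict[str, ToyGenome]
    config: SimConfig


# ---------------------------------------------------------------------------


def _chrom_weights(genome: ToyGenome, ploidy: str) -> tuple[list[str], np.ndarray]:
    copies = {AUTOSOME: {"diploid": 2, "haploid_X": 1, "haploid_Y": 1},
              SEX_X: {"diploid": 1, "haploid_X": 1, "haploid_Y": 0},
              SEX_Y: {"diploid": 1, "haploid_X": 0, "haploid_Y": 1}}
    names, w = [], []
    for c in genome.chromosomes:
        if c.cls == MITO:
            continue
        k = copies[c.cls][ploidy]
        if k > 0:
            names.append(c.name)
            w.append(k * c.length)
    w = np.asarray(w, float)
    return names, w / w.sum()


def _sample_power_law(rng, n, alpha, smin, smax):
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return smin * (smax / smin) ** u
    e = 1.0 - alpha
    return (smin**e + u * (smax**e - smin**e)) ** (1.0 / e)


def _snap_to_fragments(rng, fragmap: FragmentMap, chrom: str, pos0: np.ndarray) -> np.ndarray:
    """Move raw 0-based positions a short way inside their covering fragment,
    mimicking sonication after ligation; returns 1-based positions."""
    bounds = fragmap.fragment_bounds(chrom)
    idx = np.searchsorted(bounds, pos0, side="right") - 1
    start, end = bounds[idx], bounds[idx + 1]
    width = np.minimum(300, end - start)
    return (start + (rng.random(pos0.size) * width)).astype(np.int64) + 1


class _CellSampler:
    """Draws the contact stream of one profile (vectorized, rejection-based)."""

    def __init__(self, genomes, fragmaps, structure, cfg, rng):
        self.genomes = genomes
        self.fragmaps = fragmaps
        self.st = structure
        self.cfg = cfg
        self.rng = rng
        # eligible fragments for artifact planting, per species
        self._frag_cache: dict[str, tuple] = {}

    # -- valid contacts ----------------------------------------------------

    def _cis_positions(self, species, chrom, n, state, phase, alpha):
        cfg, rng, st = self.cfg, self.rng, self.st
        g = self.genomes[species]
        L = g.length_of(chrom)
        smax = max(cfg.min_distance * 2, L * 0.9)
        p_early = float(np.clip(0.5 + cfg.repli_bias * (0.5 - phase), 0.05, 0.95))
        bnd = st.boundaries[state][chrom]
        roi_chrom, roi_a, roi_b = st.roi
        pos1 = np.empty(0)
        pos2 = np.empty(0)
        while pos1.size < n:
            m = max(64, int((n - pos1.size) * 2.2))
            s = _sample_power_law(rng, m, alpha, cfg.min_distance, smax)
            s = np.minimum(s, L - cfg.min_distance)
            a = rng.random(m) * (L - s)
            # tilt anchors toward the phase-appropriate replication class
            want_early = rng.random(m) < p_early
            for _ in range(3):
                mism = st.is_early(chrom, a) != want_early
                if not mism.any():
                    break
                a[mism] = rng.random(mism.sum()) * (L - s[mism])
            b = a + s
            acc = np.ones(m)
            inter_tad = np.searchsorted(bnd, a) != np.searchsorted(bnd, b)
            acc[inter_tad] /= cfg.tad_weight
            diff_comp = st.compartment_label(chrom, a) != st.compartment_label(chrom, b)
            acc[diff_comp] /= cfg.compartment_weight
            if state == "melting" and chrom == roi_chrom:
                hit = (a >= roi_a) & (a < roi_b) & (s < cfg.melt_short_range)
                acc[hit] /= cfg.melt_suppression
            keep = rng.random(m) < acc
            pos1 = np.concatenate([pos1, a[keep]])
            pos2 = np.concatenate([pos2, b[keep]])
        return pos1[:n], pos2[:n]

    def valid_pairs(self, profile: SimCellProfile, n: int) -> pd.DataFrame:
        cfg, rng = self.cfg, self.rng
        g = self.genomes[profile.species_tag]
        fm = self.fragmaps[profile.species_tag]
        chroms, w = _chrom_weights(g, profile.ploidy)
        alpha = cfg.decay_exponent * (1.0 + cfg.phase_decay_shift * (profile.phase - 0.5))
        trans_rate = cfg.trans_rate
        if profile.ploidy != "diploid":
            trans_rate = min(0.95, trans_rate * cfg.haploid_trans_multiplier)
        n_trans = rng.binomial(n, trans_rate) if len(chroms) > 1 else 0
        n_cis = n - n_trans

        rows = []
        counts = rng.multinomial(n_cis, w)
        for chrom, k in zip(chroms, counts):
            if k == 0:
                continue
            a, b = self._cis_positions(profile.species_tag, chrom, k,
                                       profile.state, profile.phase, alpha)
            rows.append(pd.DataFrame({
                "chrom1": chrom, "pos1": _snap_to_fragments(rng, fm, chrom, a),
                "chrom2": chrom, "pos2": _snap_to_fragments(rng, fm, chrom, b),
            }))
        if n_trans:
            c1 = rng.choice(len(chroms), n_trans, p=w)
            c2 = rng.choice(len(chroms), n_trans, p=w)
            for _ in range(16):
                clash = c1 == c2
                if not clash.any():
                    break
                c1[clash] = rng.choice(len(chroms), clash.sum(), p=w)
                c2[clash] = rng.choice(len(chroms), clash.sum(), p=w)
            lens = np.array([g.length_of(c) for c in chroms], float)
            p1 = (rng.random(n_trans) * (lens[c1] - 1)).astype(np.int64)
            p2 = (rng.random(n_trans) * (lens[c2] - 1)).astype(np.int64)
            tdf = pd.DataFrame({
                "chrom1": np.asarray(chroms, object)[c1], "pos1": p1 + 1,
                "chrom2": np.asarray(chroms, object)[c2], "pos2": p2 + 1,
            })
            for col, chrom in (("pos1", "chrom1"), ("pos2", "chrom2")):
                for ch in tdf[chrom].unique():
                    m = tdf[chrom] == ch
                    tdf.loc[m, col] = _snap_to_fragments(
                        rng, fm, ch, tdf.loc[m, col].to_numpy(float) - 1)
            rows.append(tdf)
        df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom1", "pos1", "chrom2", "pos2"])
        # mito-nuclear false positives replace a random subset of valid pairs
        n_fp = rng.binomial(len(df), cfg.mito_fp_rate) if len(df) else 0
        is_fp = np.zeros(len(df), dtype=bool)
        if n_fp:
            idx = rng.choice(len(df), n_fp, replace=False)
            mchrom = g.mito_chrom
            mlen = g.length_of(mchrom)
            df.loc[idx, "chrom2"] = mchrom
            df.loc[idx, "pos2"] = rng.integers(1, mlen + 1, n_fp)
            is_fp[idx] = True
        df["strand1"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
        df["strand2"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
        df["true_category"] = "valid"
        df["true_mito_fp"] = is_fp
        return df

    # -- artifacts ---------------------------------------------------------

    def _eligible_fragments(self, species):
        if species not in self._frag_cache:
            fm = self.fragmaps[species]
            g = self.genomes[species]
            chroms, starts, ends = [], [], []
            adj_chroms, adj_cuts, adj_left, adj_right = [], [], [], []
            for c in g.chromosomes:
                if c.cls == MITO:
                    continue
                bounds = fm.fragment_bounds(c.name)
                ln = np.diff(bounds)
                ok = ln >= 120
                chroms.extend([c.name] * int(ok.sum()))
                starts.extend(bounds[:-1][ok])
                ends.extend(bounds[1:][ok])
                both = ok[:-1] & ok[1:]
                adj_chroms.extend([c.name] * int(both.sum()))
                adj_cuts.extend(bounds[1:-1][both])
                adj_left.extend(bounds[:-2][both])
                adj_right.extend(bounds[2:][both])
            self._frag_cache[species] = (
                np.asarray(chroms, object), np.asarray(starts), np.asarray(ends),
                np.asarray(adj_chroms, object), np.asarray(adj_cuts),
                np.asarray(adj_left), np.asarray(adj_right),
            )
        return self._frag_cache[species]

    def artifact_pairs(self, species, n_dangle, n_self, n_relig, n_dumped) -> pd.DataFrame:
        rng = self.rng
        chroms, starts, ends, a_chroms, a_cuts, a_left, a_right = self._eligible_fragments(species)
        rows = []

        def same_frag(n, strands, category):
            if n == 0:
                return
            i = rng.integers(0, len(chroms), n)
            j1 = rng.integers(0, 41, n)
            j2 = rng.integers(0, 41, n)
            p1 = starts[i] + 1 + j1
            p2 = ends[i] - j2
            p1, p2 = np.minimum(p1, p2), np.maximum(p1, p2)
            rows.append(pd.DataFrame({
                "chrom1": chroms[i], "pos1": p1, "chrom2": chroms[i], "pos2": p2,
                "strand1": strands[0], "strand2": strands[1],
                "true_category": category, "true_mito_fp": False,
            }))

        same_frag(n_dangle, ("+", "-"), "dangling_end")
        same_frag(n_self, ("-", "+"), "self_circle")
        if n_relig:
            i = rng.integers(0, len(a_chroms), n_relig)
            j1 = 1 + rng.integers(0, 40, n_relig)
            j2 = 1 + rng.integers(0, 40, n_relig)
            p1 = np.maximum(a_cuts[i] - j1, a_left[i]) + 1
            p2 = np.minimum(a_cuts[i] + j2, a_right[i] - 1) + 1
            rows.append(pd.DataFrame({
                "chrom1": a_chroms[i], "pos1": p1, "chrom2": a_chroms[i], "pos2": p2,
                "strand1": "+", "strand2": "-",
                "true_category": "religation", "true_mito_fp": False,
            }))
        if n_dumped:
            i = rng.integers(0, len(chroms), n_dumped)
            width = ends[i] - starts[i]
            p1 = starts[i] + 1 + rng.integers(0, 40, n_dumped)
            p2 = p1 + rng.integers(1, np.maximum(2, width - 60), n_dumped)
            p2 = np.minimum(p2, ends[i])
            strand = np.where(rng.random(n_dumped) < 0.5, "+", "-")
            rows.append(pd.DataFrame({
                "chrom1": chroms[i], "pos1": p1, "chrom2": chroms[i], "pos2": p2,
                "strand1": strand, "strand2": strand,
                "true_category": "dumped", "true_mito_fp": False,
            }))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    # -- full stream -------------------------------------------------------

    def cell_stream(self, profile: SimCellProfile) -> pd.DataFrame:
        cfg, rng = self.cfg, self.rng
        af = cfg.artifact_fractions
        total = profile.target_pair_count
        n_dup = rng.binomial(total, cfg.duplicate_rate)
        n_orig = total - n_dup
        n_val, n_dan, n_sel, n_rel, n_dmp = rng.multinomial(
            n_orig, [af.valid, af.dangling_end, af.self_circle, af.religation, af.dumped])
        parts = [self.valid_pairs(profile, n_val),
                 self.artifact_pairs(profile.species_tag, n_dan, n_sel, n_rel, n_dmp)]
        parts = [p for p in parts if len(p)]
        if not parts:
            df = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2",
                                       "strand1", "strand2", "true_category",
                                       "true_mito_fp"])
        else:
            df = pd.concat(parts, ignore_index=True)
        df = df.sample(frac=1.0, random_state=rng.integers(0, 2**31)).reset_index(drop=True)
        if n_dup and len(df):
            copies = df.iloc[rng.integers(0, len(df), n_dup)].copy()
            copies["true_category"] = copies["true_category"].to_numpy()
            df = pd.concat([df, copies], ignore_index=True)
        df["cell_id"] = profile.cell_id
        return df


def _draw_profiles(genomes, cfg: SimConfig, rng) -> tuple[list, list]:
    """Cell profiles plus (species list per barcode) doublet assignments."""
    species = list(cfg.n_cells)
    for s in species:
        if s not in genomes:
            raise ValueError(f"species {s!r} not present in genomes")
    singles = []
    for s, n in cfg.n_cells.items():
        singles.extend([s] * n)
    rng.shuffle(singles)
    n_barcodes = len(singles)
    is_doublet = rng.random(n_barcodes) < cfg.doublet_rate
    ploidy_names = list(cfg.ploidy_fractions)
    ploidy_p = np.array([cfg.ploidy_fractions[p] for p in ploidy_names])

    def one(species_tag, cell_id, barcode, scale=1.0):
        depth = cfg.mean_pairs_per_cell * 10 ** (rng.normal(0, cfg.log10_depth_sd))
        state = "melting" if rng.random() < cfg.melting_fraction else "concretion"
        ploidy = ploidy_names[rng.choice(len(ploidy_names), p=ploidy_p)]
        if ploidy != "diploid" and not genomes[species_tag].chroms_of_class(SEX_X):
            ploidy = "diploid"  # species without sex chromosomes stays diploid
        return SimCellProfile(barcode, cell_id, species_tag, state, ploidy,
                              float(rng.random()), max(10, int(depth * scale)))

    profiles, barcode_members = [], []
    for k, s in enumerate(singles):
        cid = f"c{k:05d}"
        bc = (k // 384, k % 384)
        if is_doublet[k] and len(species) > 1:
            other = rng.choice([x for x in species if x != s])
            members = [one(s, cid, bc), one(str(other), cid, bc)]
        else:
            members = [one(s, cid, bc)]
        profiles.append(members)
        barcode_members.append(members)
    return profiles, barcode_members


def simulate_cells(
    genomes: dict[str, ToyGenome] | None = None,
    config: SimConfig | None = None,
) -> SimResult:
    """Simulate the full barcode-tagged pair stream with ground truth."""
    cfg = config or SimConfig()
    cfg.validate()
    if genomes is None:
        # the stock genomes are a fixed reference (like a genome build),
        # independent of the simulation seed
        a, b = default_genomes(0)
        genomes = {a.species_tag: a, b.species_tag: b}
    rng = np.random.default_rng(cfg.rng_seed)
    structure = default_structure(genomes, cfg)
    fragmaps = {s: digest_genome(g) for s, g in genomes.items()}
    sampler = _CellSampler(genomes, fragmaps, structure, cfg, rng)

    barcodes, _ = _draw_profiles(genomes, cfg, rng)

    streams, truth_rows = [], []
    for members in barcodes:
        dfs = [sampler.cell_stream(p) for p in members]
        df = pd.concat(dfs, ignore_index=True)
        streams.append(df)
        lead = members[0]
        truth_rows.append(_truth_row(lead, members, df))
    # background barcodes: ambient mixture of both species at low depth;
    # drawn as two bulk streams and sliced into barcodes (one barcode has
    # no structure of its own, so bulk sampling is equivalent and fast)
    if cfg.n_background_barcodes:
        species = list(genomes)
        glen = np.array([genomes[s].total_length for s in species], float)
        glen /= glen.sum()
        per_bc = np.maximum(1, rng.poisson(cfg.background_mean_pairs,
                                           cfg.n_background_barcodes))
        totals = rng.multinomial(int(per_bc.sum()), glen)
        parts = []
        for s, kk in zip(species, totals):
            if kk == 0:
                continue
            prof = SimCellProfile((383, 383), "ambient", s, "concretion",
                                  "diploid", 0.5, int(kk))
            parts.append(sampler.cell_stream(prof))
        ambient = pd.concat(parts, ignore_index=True)
        ambient = ambient.sample(frac=1.0,
                                 random_state=rng.integers(0, 2**31))
        bg_ids = np.repeat([f"bg{k:05d}" for k in range(cfg.n_background_barcodes)],
                           per_bc)
        ambient = ambient.iloc[: len(bg_ids)].reset_index(drop=True)
        ambient["cell_id"] = bg_ids[: len(ambient)]
        streams.append(ambient)
        mix = "+".join(sorted(species))
        counts = (ambient.groupby("cell_id")["true_category"]
                  .value_counts().unstack(fill_value=0))
        fp = ambient.groupby("cell_id")["true_mito_fp"].sum()
        for k in range(cfg.n_background_barcodes):
            cid = f"bg{k:05d}"
            row_counts = counts.loc[cid] if cid in counts.index else {}
            truth_rows.append({
                "cell_id": cid,
                "bc1_idx": 383 - k // 384, "bc2_idx": 383 - k % 384,
                "type": "background", "species": mix,
                "state": "ambient", "ploidy": "ambient", "phase": np.nan,
                "n_pairs_total": int(sum(dict(row_counts).values())),
                "n_valid": int(dict(row_counts).get("valid", 0)),
                "n_dangling_end": int(dict(row_counts).get("dangling_end", 0)),
                "n_self_circle": int(dict(row_counts).get("self_circle", 0)),
                "n_religation": int(dict(row_counts).get("religation", 0)),
                "n_dumped": int(dict(row_counts).get("dumped", 0)),
                "n_mito_fp": int(fp.get(cid, 0)),
            })

    pairs = pd.concat(streams, ignore_index=True)
    pairs["mapq1"] = 60
    pairs["mapq2"] = 60
    pairs["read_id"] = [f"r{i:08d}" for i in range(len(pairs))]
    pairs = canonicalize_pairs(pairs)
    cols = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
            "mapq1", "mapq2", "cell_id", "true_category", "true_mito_fp"]
    pairs = pairs[cols]
    truth = pd.DataFrame(truth_rows)
    return SimResult(pairs, truth, structure, genomes, cfg)


def _truth_row(lead: SimCellProfile, members, df: pd.DataFrame) -> dict:
    counts = df["true_category"].value_counts()
    return {
        "cell_id": lead.cell_id,
        "bc1_idx": lead.barcode[0],
        "bc2_idx": lead.barcode[1],
        "type": "doublet" if len(members) > 1 else "cell",
        "species": "+".join(sorted({m.species_tag for m in members}))
        if len(members) > 1 else lead.species_tag,
        "state": lead.state,
        "ploidy": lead.ploidy,
        "phase": lead.phase,
        "n_pairs_total": len(df),
        "n_valid": int(counts.get("valid", 0)),
        "n_dangling_end": int(counts.get("dangling_end", 0)),
        "n_self_circle": int(counts.get("self_circle", 0)),
        "n_religation": int(counts.get("religation", 0)),
        "n_dumped": int(counts.get("dumped", 0)),
        "n_mito_fp": int(df["true_mito_fp"].sum()),
    }
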