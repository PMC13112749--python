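"""Toy genomes with restriction-site maps.

A :class:`ToyGenome` is a desk-scale stand-in for a reference assembly: a
handful of chromosomes (autosomes, sex chromosomes, one mitochondrial
contig) plus the sorted positions at which the restriction enzyme cuts.
Cut sites are drawn as a homogeneous Poisson process (exponential
inter-arrival spacing), decoupling the simulator from sequence handling;
an optional FASTA emitter plants the literal recognition motif at every
cut site in otherwise motif-free sequence so that sequence-level digestion
round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MOTIF = "GATC"

#: chromosome classes
AUTOSOME = "autosome"
SEX_X = "sex_X"
SEX_Y = "sex_Y"
MITO = "mito"


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    cls: str = AUTOSOME


@dataclass
class ToyGenome:
    """Two-column genome model: chromosome table + per-chromosome cut sites."""

    species_tag: str
    chromosomes: list[Chromosome]
    cut_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        n_mito = sum(c.cls == MITO for c in self.chromosomes)
        if n_mito != 1:
            raise ValueError(f"expected exactly one mito chromosome, got {n_mito}")
        for name, sites in self.cut_sites.items():
            length = self.length_of(name)
            sites = np.asarray(sites, dtype=np.int64)
            if sites.size and (np.any(np.diff(sites) <= 0) or sites[0] <= 0 or sites[-1] >= length):
                raise ValueError(f"cut sites of {name} must be strictly increasing in (0, length)")
            self.cut_sites[name] = sites

    def length_of(self, name: str) -> int:
        for c in self.chromosomes:
            if c.name == name:
                return c.length
        raise KeyError(name)

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def mito_chrom(self) -> str:
        return next(c.name for c in self.chromosomes if c.cls == MITO)

    def chroms_of_class(self, cls: str) -> list[str]:
        return [c.name for c in self.chromosomes if c.cls == cls]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def n_fragments(self, name: str) -> int:
        return len(self.cut_sites.get(name, ())) + 1


def build_toy_genome(
    species_tag: str,
    chrom_spec: list[Chromosome] | list[tuple],
    mean_fragment_spacing: float = 500.0,
    rng_seed: int | np.random.Generator = 0,
) -> ToyGenome:
    """Draw cut sites for each chromosome as a Poisson process.

    Parameters
    ----------
    chrom_spec
        List of :class:`Chromosome` or ``(name, length[, class])`` tuples.
    mean_fragment_spacing
        Mean distance between consecutive cut sites, bp.
    rng_seed
        Integer seed or a ready ``numpy.random.Generator``.
    """
    if mean_fragment_spacing <= 0:
        raise ValueError("mean_fragment_spacing must be positive")
    chroms = [c if isinstance(c, Chromosome) else Chromosome(*c) for c in chrom_spec]
    for c in chroms:
        if c.length <= 0:
            raise ValueError(f"chromosome {c.name} has non-positive length")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    cut_sites = {}
    for c in chroms:
        # exponential inter-arrival gaps; over-draw, then truncate to length
        n_expect = int(c.length / mean_fragment_spacing)
        gaps = rng.exponential(mean_fragment_spacing, size=max(16, int(n_expect * 1.3) + 32))
        pos = np.cumsum(gaps)
        while pos.size and pos[-1] < c.length:
            extra = rng.exponential(mean_fragment_spacing, size=64)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        sites = np.unique(pos[pos < c.length].astype(np.int64))
        sites = sites[(sites > 0) & (sites < c.length - len(MOTIF))]
        # keep sites at least one motif length apart so planted motifs
        # cannot overlap in the emitted FASTA
        keep = []
        last = -len(MOTIF)
        for s in sites:
            if s - last >= len(MOTIF):
                keep.append(s)
                last = s
        cut_sites[c.name] = np.asarray(keep, dtype=np.int64)
    return ToyGenome(species_tag, chroms, cut_sites)


def default_genomes(rng_seed: int = 0) -> tuple[ToyGenome, ToyGenome]:
    """The two stock barnyard species used throughout the test-bed.

    Species "alpha" carries sex chromosomes (for ploidy scoring); both carry
    a 16 kb mitochondrial contig (for the mito false-positive metric).
    """
    alpha_spec = [
        Chromosome("chrA1", 20_000_000, AUTOSOME),
        Chromosome("chrA2", 15_000_000, AUTOSOME),
        Chromosome("chrX", 5_000_000, SEX_X),
        Chromosome("chrY", 1_000_000, SEX_Y),
        Chromosome("chrM", 16_000, MITO),
    ]
    beta_spec = [
        Chromosome("chrB1", 18_000_000, AUTOSOME),
        Chromosome("chrB2", 12_000_000, AUTOSOME),
        Chromosome("chrMb", 16_000, MITO),
    ]
    rng = np.random.default_rng(rng_seed)
    alpha = build_toy_genome("alpha", alpha_spec, 500.0, rng)
    beta = build_toy_genome("beta", beta_spec, 500.0, rng)
    return alpha, beta


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def genome_to_fasta(genome: ToyGenome, path, rng_seed: int = 0, line_width: int = 80) -> None:
    """Write a FASTA whose only motif occurrences sit at the planted cut sites.

    Background sequence is drawn motif-free by rejection: any accidental
    occurrence of the recognition motif is destroyed by mutating one base.
    """
    rng = np.random.default_rng(rng_seed)
    motif = np.frombuffer(MOTIF.encode(), dtype="S1")
    with open(path, "w") as fh:
        for c in genome.chromosomes:
            seq = _BASES[rng.integers(0, 4, size=c.length)]
            # remove accidental motifs (repeat until clean: planting may re-create them)
            while True:
                hits = _find_motif(seq)
                hits = hits[~np.isin(hits, genome.cut_sites[c.name])]
                if hits.size == 0:
                    break
                # mutate the second base of each accidental occurrence
                seq[hits + 1] = np.where(seq[hits + 1] == b"A", b"C", b"A")
            for s in genome.cut_sites[c.name]:
                seq[s : s + len(MOTIF)] = motif
            fh.write(f">{c.name}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), line_width):
                fh.write(raw[i : i + line_width] + "\n")


def _find_motif(seq: np.ndarray) -> np.ndarray:
    """All start indices of MOTIF in a byte array (vectorized scan)."""
    if seq.size < len(MOTIF):
        return np.empty(0, dtype=np.int64)
    mask = np.ones(seq.size - len(MOTIF) + 1, dtype=bool)
    for off, b in enumerate(MOTIF.encode()):
        mask &= seq[off : seq.size - len(MOTIF) + 1 + off] == bytes([b])
    return np.flatnonzero(mask).astype(np.int64)
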