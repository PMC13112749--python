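import numpy as np
import pandas as pd
import pytest

from schicmelt.classify import FragmentMap, classify_pairs, deduplicate
from schicmelt.genome import default_genomes
from schicmelt.simulate import SimConfig, simulate_cells


@pytest.fixture(scope="session")
def genomes():
    a, b = default_genomes(0)
    return {a.species_tag: a, b.species_tag: b}


@pytest.fixture(scope="session")
def alpha(genomes):
    return genomes["alpha"]


def combined_fragment_map(genomes) -> FragmentMap:
    cuts, lengths = {}, {}
    for g in genomes.values():
        for c in g.chromosomes:
            cuts[c.name] = g.cut_sites[c.name]
            lengths[c.name] = c.length
    return FragmentMap(cuts, lengths)


@pytest.fixture(scope="session")
def fragmap(genomes):
    return combined_fragment_map(genomes)


@pytest.fixture(scope="session")
def small_sim():
    """A barnyard library small enough for fast unit tests: 30+30 cells,
    6% cross-species doublets, 200 background barcodes."""
    cfg = SimConfig(
        n_cells={"alpha": 30, "beta": 30}, doublet_rate=0.06,
        n_background_barcodes=200, mean_pairs_per_cell=1_500, rng_seed=5,
    )
    return simulate_cells(config=cfg)


@pytest.fixture(scope="session")
def small_classified(small_sim, fragmap):
    return deduplicate(classify_pairs(small_sim.pairs, fragmap))


def make_pairs(rows, cell="c0"):
    """Helper: build a pair table from (chrom1,pos1,strand1,chrom2,pos2,strand2)."""
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "strand1",
                                     "chrom2", "pos2", "strand2"])
    df["mapq1"] = 60
    df["mapq2"] = 60
    df["cell_id"] = cell
    df["read_id"] = [f"r{i}" for i in range(len(df))]
    return df
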