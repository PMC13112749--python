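import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from schicmelt.phasing import (
    RepliTrack, diploid_sex_fraction, group_compare_trans_cis, haploid_score,
    repli_score,
)

from conftest import make_pairs


def _track():
    return RepliTrack.from_intervals(
        early=[("c1", 0, 1_000_000)], late=[("c1", 1_000_000, 2_000_000)])


class TestRepliScore:
    def test_all_early_pseudocount_arithmetic(self):
        """50 pairs = 100 endpoints in early domains -> ratio 101/1."""
        pairs = make_pairs([("c1", 100 + i, "+", "c1", 200 + i, "-")
                            for i in range(50)])
        out = repli_score(pairs, _track())
        assert out["ratio"].iloc[0] == pytest.approx(101.0)

    def test_even_split_ratio_one(self):
        pairs = make_pairs([("c1", 100 + i, "+", "c1", 1_500_000 + i, "-")
                            for i in range(50)])
        out = repli_score(pairs, _track())
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_uninformative_cell_flagged(self):
        track = RepliTrack.from_intervals(early=[("c9", 0, 100)],
                                          late=[("c9", 100, 200)])
        pairs = make_pairs([("c1", 100, "+", "c1", 200, "-")])
        with pytest.warns(UserWarning, match="no\nendpoints|no endpoints"):
            out = repli_score(pairs, track)
        assert out["uninformative"].iloc[0]

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RepliTrack.from_intervals(early=[("c1", 0, 150)],
                                      late=[("c1", 100, 200)])

    def test_planted_phase_gradient_recovered(self):
        """Spearman between planted phase and repli-score rank >= 0.8."""
        from schicmelt.simulate import SimConfig, simulate_cells
        cfg = SimConfig(n_cells={"alpha": 60}, duplicate_rate=0.0,
                        mito_fp_rate=0.0, mean_pairs_per_cell=3_000, rng_seed=11)
        res = simulate_cells(config=cfg)
        v = res.pairs[res.pairs["true_category"] == "valid"]
        g = res.genomes["alpha"]
        track = RepliTrack.from_intervals(
            res.structure.repli_intervals(g, "early"),
            res.structure.repli_intervals(g, "late"))
        rs = repli_score(v, track)
        merged = rs.merge(res.truth[["cell_id", "phase"]], on="cell_id")
        rho = spearmanr(merged["phase"], merged["rank"]).statistic
        assert rho >= 0.8

    def test_ranking_invariant_to_uniform_downsampling(self):
        from schicmelt.matrix import downsample_per_cell
        from schicmelt.simulate import SimConfig, simulate_cells
        cfg = SimConfig(n_cells={"alpha": 40}, duplicate_rate=0.0,
                        mito_fp_rate=0.0, mean_pairs_per_cell=3_000,
                        log10_depth_sd=0.0, rng_seed=12)
        res = simulate_cells(config=cfg)
        v = res.pairs[res.pairs["true_category"] == "valid"]
        g = res.genomes["alpha"]
        track = RepliTrack.from_intervals(
            res.structure.repli_intervals(g, "early"),
            res.structure.repli_intervals(g, "late"))
        full = repli_score(v, track).set_index("cell_id")["rank"]
        half = repli_score(downsample_per_cell(v, int(v.groupby("cell_id").size().min() // 2),
                                               rng_seed=1), track).set_index("cell_id")["rank"]
        rho = spearmanr(full, half.reindex(full.index)).statistic
        assert rho >= 0.9


class TestHaploidScore:
    def test_diploid_copy_length_uniform_scores_one(self, alpha):
        """Endpoints drawn proportional to diploid copy-length give ~1.0."""
        rng = np.random.default_rng(0)
        chroms = ["chrA1", "chrA2", "chrX", "chrY"]
        w = np.array([2 * 20e6, 2 * 15e6, 5e6, 1e6])
        w = w / w.sum()
        rows = []
        for _ in range(20_000):
            c1, c2 = rng.choice(chroms, 2, p=w)
            rows.append((c1, int(rng.integers(1, 1000)), "+",
                         c2, int(rng.integers(1, 1000)), "-"))
        out = haploid_score(make_pairs(rows), alpha)
        assert out["score"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert out["ploidy_call"].iloc[0] == "diploid"

    def test_closed_form_diploid_fraction(self, alpha):
        # alpha: autosomes 35 Mb, X 5 Mb, Y 1 Mb
        assert diploid_sex_fraction(alpha) == pytest.approx(6 / 76)

    def test_genome_without_sex_chromosomes_rejected(self, genomes):
        with pytest.raises(ValueError, match="sex"):
            haploid_score(make_pairs([("chrB1", 1, "+", "chrB1", 500, "-")]),
                          genomes["beta"])

    def test_haploid_x_mean_matches_closed_form(self, alpha):
        """Simulated haploid-X cells (cis only, endpoints ~ haploid copy
        lengths): mean score within 5% of (L_X/(L_auto+L_X))/e_dip."""
        from schicmelt.simulate import SimConfig, simulate_cells
        cfg = SimConfig(n_cells={"alpha": 30}, trans_rate=0.0,
                        duplicate_rate=0.0, mito_fp_rate=0.0,
                        ploidy_fractions={"haploid_X": 1.0},
                        mean_pairs_per_cell=3_000, rng_seed=13)
        res = simulate_cells(config=cfg)
        v = res.pairs[res.pairs["true_category"] == "valid"]
        out = haploid_score(v, alpha)
        expect = (5 / 40) / diploid_sex_fraction(alpha)
        assert out["score"].mean() == pytest.approx(expect, rel=0.05)

    def test_haploid_vs_diploid_auc(self, alpha):
        """Score ranking separates planted ploidy with AUC >= 0.95."""
        from sklearn.metrics import roc_auc_score
        from schicmelt.simulate import SimConfig, simulate_cells
        cfg = SimConfig(n_cells={"alpha": 60}, duplicate_rate=0.0,
                        mito_fp_rate=0.0, mean_pairs_per_cell=3_000,
                        ploidy_fractions={"diploid": 0.5, "haploid_X": 0.5},
                        rng_seed=14)
        res = simulate_cells(config=cfg)
        v = res.pairs[res.pairs["true_category"] == "valid"]
        out = haploid_score(v, alpha).merge(
            res.truth[["cell_id", "ploidy"]], on="cell_id")
        auc = roc_auc_score((out["ploidy"] == "haploid_X").astype(int),
                            out["score"])
        assert auc >= 0.95

    def test_scale_invariance(self, alpha):
        rows = [("chrA1", 1 + i, "+", "chrX", 1 + i, "-") for i in range(100)]
        one = haploid_score(make_pairs(rows), alpha)["score"].iloc[0]
        three = haploid_score(make_pairs(rows * 3), alpha)["score"].iloc[0]
        assert one == pytest.approx(three)


class TestGroupCompare:
    def _qc(self, values, prefix):
        return pd.DataFrame({"cell_id": [f"{prefix}{i}" for i in range(len(values))],
                             "log2_trans_cis": values})

    def _calls(self, n_hap, n_dip):
        return pd.DataFrame({
            "cell_id": [f"h{i}" for i in range(n_hap)] + [f"d{i}" for i in range(n_dip)],
            "ploidy_call": ["haploid"] * n_hap + ["diploid"] * n_dip,
        })

    def test_identical_groups_p_near_one(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        qc = pd.concat([self._qc(vals, "h"), self._qc(vals, "d")],
                       ignore_index=True)
        out = group_compare_trans_cis(qc, self._calls(5, 5))
        assert out["p_value"] > 0.9

    def test_rank_sum_matches_exhaustive_enumeration(self):
        """4 vs 4: the Mann-Whitney U null distribution from exhaustive
        label enumeration reproduces the reported two-sided p."""
        a = np.array([1.0, 3.0, 5.0, 9.0])
        b = np.array([2.0, 4.0, 6.0, 7.0])
        pooled = np.concatenate([a, b])
        u_obs = mannwhitneyu(a, b, alternative="two-sided").statistic
        us = []
        for comb in itertools.combinations(range(8), 4):
            ga = pooled[list(comb)]
            gb = pooled[[i for i in range(8) if i not in comb]]
            u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
            us.append(u)
        us = np.asarray(us)
        mu = 8.0  # mean of U under the null for 4 vs 4
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu))
        p_scipy = mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
        assert p_scipy == pytest.approx(p_exact, abs=1e-12)

    def test_small_group_no_test(self):
        qc = pd.concat([self._qc([0.1, 0.2], "h"),
                        self._qc([0.3, 0.4, 0.5], "d")], ignore_index=True)
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = group_compare_trans_cis(qc, self._calls(2, 3))
        assert "p_value" not in out

    def test_haploid_trans_elevation_recovered(self):
        """Haploid cells simulated with doubled trans rate show a higher
        median log2 trans/cis in >= 95% of replicates."""
        import sys
        sys.path.insert(0, "tests")
        from conftest import combined_fragment_map
        from schicmelt.classify import cell_qc, classify_pairs, deduplicate
        from schicmelt.simulate import SimConfig, simulate_cells
        wins = 0
        for seed in range(10):
            cfg = SimConfig(n_cells={"alpha": 16}, duplicate_rate=0.0,
                            mito_fp_rate=0.0, mean_pairs_per_cell=1_000,
                            ploidy_fractions={"diploid": 0.5, "haploid_X": 0.5},
                            rng_seed=100 + seed)
            res = simulate_cells(config=cfg)
            fm = combined_fragment_map(res.genomes)
            qc = cell_qc(deduplicate(classify_pairs(res.pairs, fm)))
            calls = res.truth.rename(columns={"ploidy": "ploidy_call"})
            calls["ploidy_call"] = calls["ploidy_call"].map(
                {"diploid": "diploid", "haploid_X": "haploid"})
            out = group_compare_trans_cis(qc, calls)
            if out["median_haploid"] > out["median_diploid"]:
                wins += 1
        assert wins >= 9
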