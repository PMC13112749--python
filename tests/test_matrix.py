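import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import hypergeom

from schicmelt.matrix import (
    APAResult, BinnedMatrix, DEPTH_LADDER, apa, balanced_rowsum_cv,
    bin_contacts, coverage_fraction, decay_slope, distance_decay,
    downsample_pairs, downsample_per_cell, ice_balance, saturation_fit,
)

from conftest import make_pairs

LENGTHS = {"chrA1": 2_000_000, "chrA2": 1_000_000}


def _rand_pairs(n, rng, lengths=LENGTHS, cell="c0"):
    chroms = list(lengths)
    c1 = rng.choice(chroms, n)
    c2 = np.where(rng.random(n) < 0.8, c1, rng.choice(chroms, n))
    rows = []
    for a, b in zip(c1, c2):
        rows.append((a, int(rng.integers(1, lengths[a] + 1)), "+",
                     b, int(rng.integers(1, lengths[b] + 1)), "-"))
    return make_pairs(rows, cell=cell)


class TestBinContacts:
    def test_single_pair_cell_arithmetic(self):
        pairs = make_pairs([("chrA1", 100, "+", "chrA1", 60_000, "-")])
        bm = bin_contacts(pairs, 50_000, LENGTHS)
        assert bm.mat[0, 1] == 1 and bm.total() == 1

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        pairs = _rand_pairs(5_000, rng)
        bm = bin_contacts(pairs, 50_000, LENGTHS)
        assert bm.total() == 5_000

    def test_coarsening_matches_direct_binning(self):
        rng = np.random.default_rng(1)
        pairs = _rand_pairs(3_000, rng)
        fine = bin_contacts(pairs, 50_000, LENGTHS).coarsen(2)
        direct = bin_contacts(pairs, 100_000, LENGTHS)
        assert (fine.mat != direct.mat).nnz == 0

    def test_bin_size_floor(self):
        with pytest.raises(ValueError):
            bin_contacts(make_pairs([("chrA1", 1, "+", "chrA1", 2, "-")]),
                         500, LENGTHS)

    def test_out_of_bounds_position_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            bin_contacts(make_pairs([("chrA1", 3_000_000, "+", "chrA1", 1, "-")]),
                         50_000, LENGTHS)


class TestIceBalance:
    def test_equal_rowsum_matrix_is_fixed_point(self):
        n = 20
        m = sp.csr_matrix(np.triu(np.ones((n, n))))
        bm = BinnedMatrix(50_000, {"c": n * 50_000}, m)
        w = ice_balance(bm, mask_percentile=0.0)
        assert bm.converged
        np.testing.assert_allclose(w, 1.0, atol=1e-4)

    def test_converged_cv_below_tolerance(self):
        rng = np.random.default_rng(2)
        bm = bin_contacts(_rand_pairs(20_000, rng), 50_000, LENGTHS)
        ice_balance(bm)
        assert bm.converged
        assert balanced_rowsum_cv(bm) < 1e-4

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        bm = bin_contacts(_rand_pairs(10_000, rng), 50_000, LENGTHS)
        bm2 = BinnedMatrix(bm.bin_size, bm.chrom_lengths, bm.mat * 2.0)
        ice_balance(bm)
        ice_balance(bm2)
        a = bm.cis_dense("chrA1", balanced=True)
        b = bm2.cis_dense("chrA1", balanced=True)
        np.testing.assert_allclose(np.nansum(a) and a / np.nansum(a),
                                   b / np.nansum(b), atol=1e-6)

    def test_idempotent_on_balanced_matrix(self):
        rng = np.random.default_rng(4)
        bm = bin_contacts(_rand_pairs(10_000, rng), 50_000, LENGTHS)
        ice_balance(bm)
        keep = ~bm.mask
        sym = bm.symmetric().toarray()
        w = np.where(keep, bm.weights, 1.0)
        balanced = sym / np.outer(w, w)
        balanced[~keep, :] = 0.0   # bins masked in the first pass stay out
        balanced[:, ~keep] = 0.0
        bm2 = BinnedMatrix(bm.bin_size, bm.chrom_lengths,
                           sp.csr_matrix(np.triu(balanced)))
        w2 = ice_balance(bm2, mask_percentile=0.0)
        np.testing.assert_allclose(w2[keep] / np.nanmean(w2[keep]), 1.0, atol=1e-3)


class TestDistanceDecay:
    def test_single_distance_single_bin(self):
        pairs = make_pairs([("chrA1", 1, "+", "chrA1", 10_001, "-")] * 10)
        curve = distance_decay(pairs)
        assert (curve["prob"] > 0).sum() == 1
        assert curve["prob"].sum() == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        curve = distance_decay(_rand_pairs(5_000, rng))
        assert curve["prob"].sum() == pytest.approx(1.0)

    def test_planted_power_law_slope(self):
        """Distances drawn from p(s) ~ 1/s on [1 kb, 10 Mb]: fitted log-log
        density slope is -1 +- 0.1."""
        rng = np.random.default_rng(6)
        n = 200_000
        s = (1e3 * (1e7 / 1e3) ** rng.random(n)).astype(np.int64)
        pos1 = rng.integers(1, 20_000_000 - s - 1)
        pairs = pd.DataFrame({
            "chrom1": "chrA1", "pos1": pos1, "strand1": "+",
            "chrom2": "chrA1", "pos2": pos1 + s, "strand2": "-",
            "cell_id": "c0",
        })
        slope = decay_slope(distance_decay(pairs), fit_range=(2e3, 5e6))
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_no_cis_pairs_warns_empty(self):
        pairs = make_pairs([("chrA1", 1, "+", "chrA2", 1, "-")])
        with pytest.warns(UserWarning):
            assert distance_decay(pairs).empty


class TestDownsample:
    def test_full_size_identity(self):
        rng = np.random.default_rng(7)
        pairs = _rand_pairs(100, rng)
        out = downsample_pairs(pairs, 100, rng_seed=0)
        pd.testing.assert_frame_equal(out, pairs.reset_index(drop=True))

    def test_over_request_rejected(self):
        with pytest.raises(ValueError, match="available"):
            downsample_pairs(_rand_pairs(10, np.random.default_rng(8)), 11)

    def test_deterministic_under_seed(self):
        pairs = _rand_pairs(1_000, np.random.default_rng(9))
        a = downsample_pairs(pairs, 300, rng_seed=5)
        b = downsample_pairs(pairs, 300, rng_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_sampled_fractions_hypergeometric(self):
        """Category balance of the sample within 3 sigma hypergeometric."""
        rng = np.random.default_rng(10)
        pairs = _rand_pairs(10_000, rng)
        cis_total = int((pairs["chrom1"] == pairs["chrom2"]).sum())
        n = 2_000
        out = downsample_pairs(pairs, n, rng_seed=1)
        cis_got = int((out["chrom1"] == out["chrom2"]).sum())
        sd = hypergeom(10_000, cis_total, n).std()
        assert abs(cis_got - hypergeom(10_000, cis_total, n).mean()) <= 3 * sd

    def test_per_cell_equalization(self):
        rng = np.random.default_rng(11)
        pairs = pd.concat([_rand_pairs(500, rng, cell="a"),
                           _rand_pairs(200, rng, cell="b"),
                           _rand_pairs(50, rng, cell="c")], ignore_index=True)
        out = downsample_per_cell(pairs, 100, rng_seed=0)
        sizes = out.groupby("cell_id").size()
        assert set(sizes.index) == {"a", "b"} and (sizes == 100).all()


class TestSaturationFit:
    def test_noiseless_recovery_on_standard_ladder(self):
        """Exact-model data at the 9-depth ladder: parameters within 0.1%."""
        bmax, kd = 1e6, 2e5
        x = np.array(DEPTH_LADDER, float)
        fit = saturation_fit(x, bmax * x / (kd + x))
        assert fit.bmax == pytest.approx(bmax, rel=1e-3)
        assert fit.kd == pytest.approx(kd, rel=1e-3)

    def test_two_point_closed_form(self):
        """On two noiseless points (plus their midpoint on the curve) the
        fit equals the closed-form inversion."""
        bmax, kd = 5e5, 1e5
        x = np.array([1e5, 4e5, 2e5])
        y = bmax * x / (kd + x)
        # closed form from points (x1,y1),(x2,y2):
        x1, x2, y1, y2 = x[0], x[1], y[0], y[1]
        kd_cf = x1 * x2 * (y2 - y1) / (x2 * y1 - x1 * y2)
        bmax_cf = y1 * (kd_cf + x1) / x1
        fit = saturation_fit(x, y)
        assert fit.kd == pytest.approx(kd_cf, rel=1e-6)
        assert fit.bmax == pytest.approx(bmax_cf, rel=1e-6)

    def test_noisy_recovery_median_error(self):
        """2% multiplicative noise, 20 seeds: median relative error <= 5%."""
        bmax, kd = 1e6, 2e5
        x = np.array(DEPTH_LADDER, float)
        errs_b, errs_k = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = bmax * x / (kd + x) * (1 + 0.02 * rng.standard_normal(len(x)))
            fit = saturation_fit(x, y)
            errs_b.append(abs(fit.bmax - bmax) / bmax)
            errs_k.append(abs(fit.kd - kd) / kd)
        assert np.median(errs_b) <= 0.05 and np.median(errs_k) <= 0.05

    def test_fitted_curve_monotone(self):
        rng = np.random.default_rng(12)
        x = np.array(DEPTH_LADDER, float)
        y = 1e6 * x / (2e5 + x) * (1 + 0.05 * rng.standard_normal(len(x)))
        fit = saturation_fit(x, y)
        pred = fit.predict(np.sort(x))
        assert (np.diff(pred) >= 0).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            saturation_fit([1e5, 2e5], [1, 2])
        with pytest.raises(ValueError):
            saturation_fit([1e5, 2e5, 4e5], [0, 0, 0])


class TestCoverage:
    def test_full_coverage_is_one(self):
        rows = [("chrA1", 25_000 + 50_000 * i, "+", "chrA1", 25_000 + 50_000 * i, "-")
                for i in range(40)] + \
               [("chrA2", 25_000 + 50_000 * i, "+", "chrA2", 25_000 + 50_000 * i, "-")
                for i in range(20)]
        table = coverage_fraction({"c0": make_pairs(rows)}, [50_000], [60], LENGTHS)
        assert table["fraction"].iloc[0] == pytest.approx(1.0)

    def test_monotone_in_depth_and_bin_size(self):
        rng = np.random.default_rng(13)
        pairs = _rand_pairs(4_000, rng)
        table = coverage_fraction({"c0": pairs}, [10_000, 50_000],
                                  [500, 2_000], LENGTHS, rng_seed=0)
        piv = table.pivot_table(index="bin_size", columns="threshold",
                                values="fraction")
        assert (piv[2_000] >= piv[500]).all()          # deeper -> more coverage
        assert (piv.loc[50_000] >= piv.loc[10_000]).all()  # coarser -> more


class TestAPA:
    def _uniform_bm(self, n=60, value=2.0):
        m = sp.csr_matrix(np.triu(np.full((n, n), value)))
        return BinnedMatrix(25_000, {"c": n * 25_000}, m)

    def _loops(self, bi, bj, bin_size=25_000):
        return pd.DataFrame([{
            "chrom1": "c", "start1": bi * bin_size, "end1": (bi + 1) * bin_size,
            "chrom2": "c", "start2": bj * bin_size, "end2": (bj + 1) * bin_size,
        }])

    def test_constant_matrix_enrichment_one(self):
        res = apa(self._uniform_bm(), self._loops(20, 40), balanced=False)
        assert res.enrichment == pytest.approx(1.0)

    def test_planted_5x_pixel(self):
        bm = self._uniform_bm()
        bm.mat = bm.mat.tolil()
        bm.mat[20, 40] = 10.0   # 5x the 2.0 background
        bm.mat = bm.mat.tocsr()
        res = apa(bm, self._loops(20, 40), balanced=False)
        assert res.enrichment == pytest.approx(5.0, rel=1e-6)

    def test_edge_loops_excluded_with_error(self):
        bm = self._uniform_bm()
        with pytest.raises(ValueError, match="eligible"):
            apa(bm, self._loops(1, 5), balanced=False)

    def test_simulated_loops_enriched(self):
        """Loop-anchored extra contacts yield enrichment > 1 in >= 95% of
        seeded replicates."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 80
            base = rng.poisson(3.0, (n, n))
            loops = [(20, 45), (30, 60)]
            for bi, bj in loops:
                base[bi, bj] += rng.poisson(12)
            m = sp.csr_matrix(np.triu(base))
            bm = BinnedMatrix(25_000, {"c": n * 25_000}, m)
            loop_df = pd.concat([self._loops(bi, bj) for bi, bj in loops],
                                ignore_index=True)
            if apa(bm, loop_df, balanced=False).enrichment > 1:
                wins += 1
        assert wins >= 19
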