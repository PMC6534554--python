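"""Cutting-efficiency estimation: classification, pooling, uncertainty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dsbquant.io_formats import CutSite, Genome
from dsbquant.efficiency import (
    BackgroundEstimate,
    CutSiteCounts,
    classify_fragments,
    classify_fragments_at_site,
    estimate_background,
    linearity_check,
    poisson_sd,
    pooled_efficiency,
    qpcr_efficiency,
    site_efficiency,
)

from conftest import make_fragments

SITE = CutSite("chr1", 150, vicinity_w=3)


class TestClassify:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (100, 200, "uncut"),   # spans the vicinity, both ends outside
            (100, 151, "cut"),     # right end 151 within [147, 153]
            (147, 250, "cut"),     # left end inside
            (100, 140, "none"),    # no contact with the vicinity
            (146, 250, "uncut"),   # overlaps but left end just outside
        ],
    )
    def test_rule(self, start, end, expected):
        counts = classify_fragments_at_site(
            make_fragments([("chr1", start, end)]), SITE, w=3
        )
        got = (
            "cut" if counts.n_cut == 1
            else "uncut" if counts.n_uncut == 1
            else "none"
        )
        assert got == expected

    def test_negative_w_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            classify_fragments_at_site(make_fragments([("chr1", 0, 10)]), SITE, w=-1)

    def test_each_fragment_counted_once(self):
        # both ends in the vicinity: counted as one cut fragment
        counts = classify_fragments_at_site(
            make_fragments([("chr1", 148, 152)]), SITE, w=3
        )
        assert (counts.n_cut, counts.n_uncut) == (1, 0)


class TestSiteEfficiency:
    def test_half(self):
        assert site_efficiency(CutSiteCounts(SITE, 100, 50), 0.0) == pytest.approx(0.5)

    def test_zero_cut(self):
        assert site_efficiency(CutSiteCounts(SITE, 0, 50), 0.1) == 0.0

    def test_complete_digestion(self):
        assert site_efficiency(CutSiteCounts(SITE, 100, 0), 0.0) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            site_efficiency(CutSiteCounts(SITE, 0, 0))

    @given(
        nc=hst.integers(1, 500),
        nu=hst.integers(1, 500),
        dc=hst.integers(1, 50),
        fbg=hst.floats(0, 0.2),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotonicity(self, nc, nu, dc, fbg):
        """More cut fragments raise f; more uncut or higher f_bg lower it."""
        base = site_efficiency(CutSiteCounts(SITE, nc, nu), fbg)
        assert site_efficiency(CutSiteCounts(SITE, nc + dc, nu), fbg) >= base
        assert site_efficiency(CutSiteCounts(SITE, nc, nu + dc), fbg) <= base
        assert site_efficiency(CutSiteCounts(SITE, nc, nu), fbg + 0.01) <= base


class TestPooled:
    def test_two_sites_pool_to_half(self):
        counts = [
            CutSiteCounts(CutSite("chr1", 100), 100, 50),
            CutSiteCounts(CutSite("chr1", 5000), 300, 150),
        ]
        est = pooled_efficiency(counts, 0.0, min_reads=100)
        assert est.f_cut == pytest.approx(400 / (400 + 2 * 200))
        assert est.n_sites_used == 2

    def test_shallow_site_excluded(self):
        counts = [
            CutSiteCounts(CutSite("chr1", 100), 200, 100),
            CutSiteCounts(CutSite("chr1", 5000), 7, 3),  # 10 fragments only
        ]
        est = pooled_efficiency(counts, 0.0, min_reads=100)
        assert est.n_sites_used == 1
        assert est.f_cut == pytest.approx(200 / 400)
        assert not est.per_site.loc[1, "passed"]

    def test_nonpositive_efficiency_site_excluded(self):
        counts = [
            CutSiteCounts(CutSite("chr1", 100), 200, 100),
            CutSiteCounts(CutSite("chr1", 5000), 0, 500),  # deep but f = 0
        ]
        est = pooled_efficiency(counts, 0.0)
        assert est.n_sites_used == 1
        assert est.per_site.loc[1, "reason"] == "efficiency <= 0"

    def test_single_passing_site_equals_site_efficiency(self):
        counts = [CutSiteCounts(CutSite("chr1", 100), 150, 75)]
        est = pooled_efficiency(counts, 0.02)
        assert est.f_cut == pytest.approx(site_efficiency(counts[0], 0.02))

    def test_no_passing_site_is_error(self):
        with pytest.raises(ValueError, match="no site passed"):
            pooled_efficiency([CutSiteCounts(SITE, 5, 5)], 0.0, min_reads=100)

    def test_sigma_total_combines_in_quadrature(self):
        bg = BackgroundEstimate(f_bg=0.01, sigma_bg=0.02, n_windows=1000, window_size=7, seed=0)
        est = pooled_efficiency([CutSiteCounts(SITE, 500, 400)], bg)
        assert est.sigma_total == pytest.approx(
            np.sqrt(est.sigma_poisson**2 + 0.02**2)
        )


class TestPoissonSD:
    def test_balanced_counts(self):
        # (110/290 - 90/310) / 2
        sd = poisson_sd(CutSiteCounts(SITE, 100, 100))
        assert sd == pytest.approx(0.5 * (110 / 290 - 90 / 310))
        assert sd == pytest.approx(0.0445, abs=1e-4)

    def test_shrinks_with_depth(self):
        sd = poisson_sd(CutSiteCounts(SITE, 10**6, 10**6))
        assert sd == pytest.approx(4.5e-4, rel=0.02)
        # ~1/sqrt(N) scaling
        sd4 = poisson_sd(CutSiteCounts(SITE, 4 * 10**6, 4 * 10**6))
        assert sd4 == pytest.approx(sd / 2, rel=0.01)

    def test_zero_uncut_rejected(self):
        with pytest.raises(ValueError):
            poisson_sd(CutSiteCounts(SITE, 10**4, 0))


class TestQpcr:
    @pytest.mark.parametrize("dct,expected", [(1, 0.5), (0, 0.0), (3, 0.875)])
    def test_point_values(self, dct, expected):
        assert qpcr_efficiency(20.0 + dct, 20.0) == pytest.approx(expected)

    def test_mean_over_dilutions(self):
        got = qpcr_efficiency(np.array([21.0, 23.0]), np.array([20.0, 20.0]))
        assert got == pytest.approx((0.5 + 0.875) / 2)

    def test_negative_dct_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="anomaly"):
            assert qpcr_efficiency(19.0, 20.0) == 0.0

    def test_calibration_offset(self):
        assert qpcr_efficiency(20.0, 20.0, calibration_offset=1.0) == pytest.approx(0.5)

    def test_nonpositive_cycles_rejected(self):
        with pytest.raises(ValueError):
            qpcr_efficiency(0.0, 20.0)


class TestBackground:
    def test_no_fragment_ends_anywhere_gives_zero(self):
        g = Genome({"chr1": "A" * 50_000})
        # one giant spanning fragment: every window sees only uncut
        frags = make_fragments([("chr1", 0, 50_000)])
        bg = estimate_background(frags, g, 7, n_windows=200, seed=1)
        assert bg.f_bg == 0.0

    def test_deterministic_given_seed(self):
        g = Genome({"chr1": "A" * 50_000})
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 49_000, 2000)
        frags = make_fragments([("chr1", int(s), int(s) + 400) for s in starts])
        a = estimate_background(frags, g, 7, 500, seed=9)
        b = estimate_background(frags, g, 7, 500, seed=9)
        assert (a.f_bg, a.sigma_bg) == (b.f_bg, b.sigma_bg)

    def test_matches_exhaustive_window_oracle(self):
        """Sampled-window mean within 3 SE of the all-windows mean."""
        g = Genome({"chr1": "A" * 100_000})
        rng = np.random.default_rng(11)
        starts = rng.integers(0, 99_500, 5000)
        frags = make_fragments([("chr1", int(s), int(s) + 400) for s in starts])

        # oracle: every window center, brute-force ratio
        s_arr = np.array(sorted(int(s) for s in starts))
        e_arr = s_arr + 400
        vals = []
        for center in range(100, 99_900, 37):  # dense deterministic grid
            lo, hi = center - 3, center + 3
            cut = ((s_arr >= lo) & (s_arr <= hi)) | ((e_arr >= lo) & (e_arr <= hi))
            uncut = (s_arr < lo) & (e_arr > hi) & ~cut
            nc, nu = int(cut.sum()), int(uncut.sum())
            vals.append(nc / (nc + 2 * nu) if nc + nu else 0.0)
        oracle_mean = np.mean(vals)

        bg = estimate_background(frags, g, 7, n_windows=1500, seed=2)
        se = bg.sigma_bg / np.sqrt(bg.n_windows)
        assert abs(bg.f_bg - oracle_mean) < 3 * se + 1e-4

    def test_window_larger_than_genome_rejected(self):
        g = Genome({"chr1": "ACGT"})
        with pytest.raises(ValueError, match="shorter than"):
            estimate_background(make_fragments([("chr1", 0, 2)]), g, 100)


class TestLinearity:
    def test_perfectly_proportional(self):
        pairs = [(100.0 * f, f) for f in (0.1, 0.2, 0.3, 0.4)]
        out = linearity_check(pairs)
        assert out["r"] == pytest.approx(1.0)
        assert not out["weak_linearity"]

    def test_constant_vector_gives_missing_r(self):
        out = linearity_check([(5.0, 0.3), (5.0, 0.3), (5.0, 0.3)])
        assert np.isnan(out["r"])
        assert out["weak_linearity"]

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            linearity_check([(1.0, 0.1), (2.0, 0.2)])


class TestRecoveryOnSimulation:
    def test_estimate_within_3_sigma_in_most_replicates(self, small_genome_with_sites):
        """|estimated - planted f_cut| <= 3 sigma_total in >= 49/50 seeded runs."""
        genome, sites = small_genome_with_sites
        from dsbquant.simulate import simulate_gdna

        hits = 0
        for seed in range(50):
            frags, truth = simulate_gdna(
                genome, sites, 0.3, coverage=1500, seed=seed
            )
            counts = classify_fragments(frags, sites)
            bg = estimate_background(
                frags, genome, 7, n_windows=500, seed=seed, exclude_sites=sites
            )
            est = pooled_efficiency(counts, bg)
            if abs(est.f_cut - 0.3) <= 3 * est.sigma_total:
                hits += 1
        assert hits >= 49
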