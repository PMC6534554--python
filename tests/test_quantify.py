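"""Spike-in quantification: alpha calibration, filtering, tracks."""

import numpy as np
import pandas as pd
import pytest

from dsbquant.io_formats import CutSite, Genome, GenomicInterval
from dsbquant.quantify import (
    compare_samples_poisson,
    count_reads_at_sites,
    filter_studied_reads,
    is_telomeric_sequence,
    per_site_sd,
    propagated_sd,
    quantify,
    remove_replication_background,
    spike_in_breaks,
    window_density,
)

from conftest import make_reads


class TestSpikeInBreaks:
    def test_in_vivo_mixing(self):
        # 71% efficiency, single site, 2:98 mixing
        assert spike_in_breaks(0.71, 1, 0.02) == pytest.approx(0.0142)

    def test_full_digestion(self):
        assert spike_in_breaks(0.5, 2, 1.0) == pytest.approx(1.0)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            spike_in_breaks(0.5, 1, 0.0)

    def test_zero_efficiency_chains_to_error(self):
        b_cut = spike_in_breaks(0.0, 10, 1.0)
        assert b_cut == 0.0
        with pytest.raises(ValueError, match="B_cut"):
            quantify(100, 100, b_cut)


class TestCountReadsAtSites:
    SITES = [CutSite("chr1", 100, vicinity_w=3)]

    def test_reads_at_cut(self):
        reads = make_reads([("chr1", 100, 150, "+")] * 10)
        assert count_reads_at_sites(reads, self.SITES, 3) == 10

    def test_boundary_exclusive(self):
        inside = make_reads([("chr1", 103, 150, "+")])
        outside = make_reads([("chr1", 104, 150, "+")])
        assert count_reads_at_sites(inside, self.SITES, 3) == 1
        assert count_reads_at_sites(outside, self.SITES, 3) == 0

    def test_crick_read_uses_five_prime_end(self):
        # minus-strand read [50, 101): 5' end at 100 == cut
        reads = make_reads([("chr1", 50, 101, "-")])
        assert count_reads_at_sites(reads, self.SITES, 3) == 1

    def test_tie_assigned_to_lower_site_once(self):
        sites = [CutSite("chr1", 100), CutSite("chr1", 104)]
        reads = make_reads([("chr1", 102, 150, "+")])  # equidistant
        total, per_site = count_reads_at_sites(reads, sites, 3, per_site=True)
        assert total == 1
        assert per_site.tolist() == [1, 0]


class TestTelomereRule:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("CACCACAC", True),        # repeats of the AC-rich unit
            ("ACGTACGT", False),
            ("ACCCCCCCCCC", True),     # single unit AC{1,10}
            ("GTGGTGGT", True),        # reverse complement orientation
            ("CCCCACAC", False),       # C{4} prefix breaks the unit rule
            (None, False),
        ],
    )
    def test_whole_read_match(self, seq, expected):
        assert is_telomeric_sequence(seq) is expected

    def test_regex_oracle(self):
        """Agreement with an independent regex on random AC-rich strings."""
        import re

        oracle = re.compile(r"^(C{0,3}AC{1,10})+$")
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = "".join(rng.choice(list("AC"), size=rng.integers(2, 30)))
            from dsbquant.io_formats import reverse_complement

            expected = bool(oracle.match(s) or oracle.match(reverse_complement(s)))
            assert is_telomeric_sequence(s) is expected


class TestFilterStudiedReads:
    GENOME_SITES = [CutSite("chr1", 500, vicinity_w=3)]

    def test_category_counts_sum(self):
        reads = make_reads(
            [("chr1", 500, 550, "+")] * 10          # at site
            + [("chr1", 2000, 2008, "+", "CACCACAC")] * 5   # telomeric
            + [("chr1", 3000, 3050, "+")] * 5       # in mask
            + [("chr1", 7000, 7050, "+")] * 80      # studied
        )
        audit = filter_studied_reads(
            reads,
            self.GENOME_SITES,
            3,
            masks=[GenomicInterval("chr1", 2900, 3100)],
        )
        assert audit.removed_at_sites == 10
        assert audit.removed_telomeric == 5
        assert audit.removed_masked == 5
        assert audit.r_studied == 80
        assert (
            audit.removed_at_sites + audit.removed_telomeric + audit.removed_masked
            + audit.r_studied
            == audit.n_input
        )

    def test_priority_site_over_telomere_over_mask(self):
        # a telomeric-sequence read at the cut counts as a site read
        reads = make_reads([("chr1", 500, 508, "+", "CACCACAC")])
        audit = filter_studied_reads(
            reads, self.GENOME_SITES, 3,
            masks=[GenomicInterval("chr1", 400, 600)],
        )
        assert audit.removed_at_sites == 1
        assert audit.removed_telomeric == 0
        assert audit.removed_masked == 0


class TestQuantify:
    def test_arithmetic_chain(self):
        q = quantify(r_studied=7_650_000, r_cut=710, b_cut=0.0142)
        assert q.alpha == pytest.approx(50_000)
        assert q.b_studied == pytest.approx(153)

    def test_zero_studied_reads(self):
        assert quantify(0, 100, 1.0).b_studied == 0.0

    def test_depth_scale_invariance(self):
        a = quantify(1000, 100, 1.0)
        b = quantify(2000, 200, 1.0)
        assert a.b_studied == pytest.approx(b.b_studied)

    def test_no_spike_signal_rejected(self):
        with pytest.raises(ValueError, match="no spike-in signal"):
            quantify(100, 0, 1.0)


class TestPerSiteSD:
    def test_identical_sites_zero_sd(self):
        sd, _ = per_site_sd(np.array([50.0, 50.0]), np.array([0.3, 0.3]), 1.0, 1000)
        assert sd == 0.0

    def test_two_sites_sample_sd(self):
        # B_1 = 10, B_2 = 20 by construction
        r_studied = 100.0
        f = np.array([0.1, 0.2])
        r_cut = r_studied * f / np.array([10.0, 20.0])
        sd, b = per_site_sd(r_cut, f, 1.0, r_studied)
        assert sorted(b.round(6)) == [10.0, 20.0]
        assert sd == pytest.approx(np.std([10, 20], ddof=1))
        assert sd == pytest.approx(7.07, abs=0.01)

    def test_single_site_rejected_then_propagated(self):
        with pytest.raises(ValueError, match=">= 2 sites"):
            per_site_sd(np.array([50.0]), np.array([0.3]), 1.0, 1000)
        # fallback path: relative error of f carries over to B
        assert propagated_sd(100.0, 0.5, 0.05) == pytest.approx(10.0)


class TestWindowDensity:
    GENOME = Genome({"chr1": "A" * 2000})

    def test_density_arithmetic(self):
        reads = make_reads([("chr1", i, i + 10, "+") for i in range(100, 150)])
        track = window_density(reads, self.GENOME, alpha=1000, window=500, step=500)
        assert track.loc[0, "value"] == pytest.approx(0.05)
        per_million = window_density(
            reads, self.GENOME, 1000, 500, 500, scale="per_million_cells"
        )
        assert per_million.loc[0, "value"] == pytest.approx(50_000)

    def test_empty_window_zero(self):
        reads = make_reads([("chr1", 1500, 1510, "+")])
        track = window_density(reads, self.GENOME, 100, 500, 500)
        assert track.loc[0, "value"] == 0.0

    def test_non_overlapping_conservation(self):
        rng = np.random.default_rng(1)
        reads = make_reads(
            [("chr1", int(p), int(p) + 10, "+") for p in rng.integers(0, 1900, 300)]
        )
        track = window_density(reads, self.GENOME, alpha=1.0, window=500, step=500)
        assert track["value"].sum() == len(reads)


class TestBackgroundRemoval:
    def _track(self, values):
        starts = np.arange(len(values)) * 500
        return pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 500, "value": values}
        )

    def test_discrete_mode_subtracted(self):
        out = remove_replication_background(self._track([2, 2, 2, 5, 2]))
        assert out["value"].tolist() == [0, 0, 0, 3, 0]

    def test_constant_track_zeroed(self):
        out = remove_replication_background(self._track([4.0] * 10))
        assert (out["value"] == 0).all()

    def test_no_negative_output(self):
        rng = np.random.default_rng(2)
        out = remove_replication_background(self._track(rng.uniform(0, 5, 200)))
        assert (out["value"] >= 0).all()

    def test_planted_baseline_recovered_within_bin(self):
        rng = np.random.default_rng(3)
        base = 2.0
        values = base + rng.normal(0, 0.1, 1000)
        values[::50] += 10  # sparse peaks
        out = remove_replication_background(self._track(values))
        # non-peak windows should drop to ~0 within one FD bin width
        edges = np.histogram_bin_edges(values, bins="fd")
        bin_w = edges[1] - edges[0]
        nonpeak = np.ones(1000, bool)
        nonpeak[::50] = False
        assert np.median(out["value"].to_numpy()[nonpeak]) <= bin_w

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            remove_replication_background(self._track([]))


class TestCompareSamples:
    GENOME = Genome({"chr1": "A" * 10_000})

    def _uniform_reads(self, n, seed):
        rng = np.random.default_rng(seed)
        return make_reads(
            [("chr1", int(p), int(p) + 10, "+") for p in rng.integers(0, 9000, n)]
        )

    def test_poisson_threshold_arithmetic(self):
        # control 4 reads in the window -> threshold 4 + 5*2 = 14
        control = make_reads([("chr1", 100 + i, 160 + i, "+") for i in range(4)])
        treated15 = make_reads([("chr1", 200 + i, 260 + i, "+") for i in range(15)])
        out = compare_samples_poisson(
            control, treated15, self.GENOME, 1.0, 1.0, k_sd=5, window=5000
        )
        assert bool(out.loc[0, "enriched"])
        treated14 = make_reads([("chr1", 200 + i, 260 + i, "+") for i in range(14)])
        out2 = compare_samples_poisson(
            control, treated14, self.GENOME, 1.0, 1.0, k_sd=5, window=5000
        )
        assert not bool(out2.loc[0, "enriched"])

    def test_identical_samples_unflagged(self):
        reads = self._uniform_reads(500, 4)
        out = compare_samples_poisson(reads, reads, self.GENOME, 1.0, 1.0)
        assert not out["enriched"].any()

    def test_alpha_normalization_applied(self):
        """A deeper treated library is rescaled before comparison."""
        control = self._uniform_reads(500, 5)
        treated = self._uniform_reads(5000, 6)  # 10x depth, same biology
        out = compare_samples_poisson(
            control, treated, self.GENOME, alpha_control=1.0, alpha_treated=10.0
        )
        assert not out["enriched"].any()
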