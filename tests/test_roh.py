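"""Run detection, shared-region intersection, autozygosity refinement, ranking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from autozygomap.genotypes import ConfigError
from autozygomap.roh import (
    SharedRegion,
    autozygosity_refine,
    find_sample_runs,
    map_regions,
    rank_regions,
    shared_regions,
)
from conftest import make_matrix, random_rows
from oracles import (
    oracle_inrun_mask,
    oracle_refine,
    oracle_runs,
    oracle_support_intervals,
)
from autozygomap.genotypes import AnalysisConfig


def _runs_as_triples(runs):
    return [(r.chrom, r.start_idx, r.end_idx) for r in runs]


class TestFindSampleRuns:
    def test_single_long_run_with_flanks(self):
        m = make_matrix(["A" * 20 + "H"])
        runs = find_sample_runs(m, "S1", min_run=15)
        assert len(runs) == 1
        r = runs[0]
        assert (r.start_idx, r.end_idx, r.n_markers) == (0, 19, 20)
        assert r.start_bp == 10 and r.end_bp == 200
        assert r.n_called == 20

    def test_below_threshold_dropped(self):
        m = make_matrix(["A" * 14 + "H" + "G" * 14])
        assert find_sample_runs(m, "S1", min_run=15) == []

    def test_all_het_chromosome(self):
        m = make_matrix(["H" * 30])
        assert find_sample_runs(m, "S1", min_run=15) == []

    def test_runs_do_not_cross_chromosomes(self):
        m = make_matrix(["A" * 10 + "G" * 10],
                        chroms=["chr1"] * 10 + ["chr2"] * 10)
        runs = find_sample_runs(m, "S1", min_run=5)
        assert _runs_as_triples(runs) == [("chr1", 0, 9), ("chr2", 10, 19)]

    def test_nocall_only_run_kept(self):
        """A run made purely of no-calls survives (homozygous deletions)."""
        m = make_matrix(["H" + "." * 16 + "H"])
        runs = find_sample_runs(m, "S1", min_run=15)
        assert len(runs) == 1 and runs[0].n_called == 0

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 200), st.integers(1, 20))
    def test_matches_bruteforce_oracle(self, seed, n_sites, min_run):
        rng = np.random.default_rng(seed)
        rows = random_rows(rng, 1, n_sites, p_het=0.4)
        split = n_sites // 2
        chroms = ["chr1"] * split + ["chr2"] * (n_sites - split)
        m = make_matrix(rows, chroms=chroms)
        codes = list(m.row_codes("S1"))
        expected = oracle_runs(codes, m.chrom_blocks, min_run)
        assert _runs_as_triples(find_sample_runs(m, "S1", min_run)) == expected


class TestSharedRegions:
    def test_identical_runs_give_the_run(self):
        row = "H" + "A" * 20 + "H"
        m = make_matrix([row, row])
        regions = shared_regions(m, ["S1", "S2"], min_patients=2, min_run=15)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_idx, r.end_idx) == (1, 20)
        assert r.supporting_patients == ("S1", "S2")
        assert r.mode == "homozygous"

    def test_disjoint_runs_give_nothing(self):
        m = make_matrix(["A" * 20 + "H" * 20,
                         "H" * 20 + "A" * 20])
        assert shared_regions(m, ["S1", "S2"], 2, 15) == []

    def test_overlap_intersection(self):
        """Runs at indices 0-39 and 20-59 intersect to 20-39."""
        r1 = "A" * 40 + "H" * 20
        r2 = "H" * 20 + "A" * 40
        m = make_matrix([r1, r2])
        regions = shared_regions(m, ["S1", "S2"], 2, 15)
        assert [(r.start_idx, r.end_idx) for r in regions] == [(20, 39)]

    def test_single_patient_reduces_to_runs(self):
        rng = np.random.default_rng(7)
        m = make_matrix(random_rows(rng, 1, 150, p_het=0.3))
        runs = find_sample_runs(m, "S1", 10)
        regions = shared_regions(m, ["S1"], 1, 10)
        assert [(r.start_idx, r.end_idx) for r in regions] == \
               [(r.start_idx, r.end_idx) for r in runs]

    def test_min_patients_out_of_range(self):
        m = make_matrix(["A" * 20])
        with pytest.raises(ConfigError):
            shared_regions(m, ["S1"], min_patients=2, min_run=15)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 4), st.integers(30, 150),
           st.integers(1, 4))
    def test_matches_support_oracle(self, seed, n_samples, n_sites, k):
        rng = np.random.default_rng(seed)
        k = min(k, n_samples)
        m = make_matrix(random_rows(rng, n_samples, n_sites, p_het=0.25))
        min_run = 8
        masks = [oracle_inrun_mask(list(m.row_codes(s)), m.chrom_blocks, min_run)
                 for s in m.samples]
        expected = oracle_support_intervals(masks, m.chrom_blocks, k, min_run)
        got = shared_regions(m, m.samples, k, min_run)
        assert [(r.chrom, r.start_idx, r.end_idx) for r in got] == expected

    @given(st.integers(0, 2 ** 31 - 1))
    def test_lower_min_patients_never_shrinks_coverage(self, seed):
        """Markers covered at support k are covered at support k-1 too."""
        rng = np.random.default_rng(seed)
        m = make_matrix(random_rows(rng, 3, 120, p_het=0.25))

        def covered(k):
            out = set()
            for r in shared_regions(m, m.samples, k, 8):
                out.update(range(r.start_idx, r.end_idx + 1))
            return out

        assert covered(3) <= covered(2) <= covered(1)


class TestAutozygosityRefine:
    def _one_region(self, m, patients, min_run=15):
        regions = shared_regions(m, patients, len(patients), min_run)
        assert len(regions) == 1
        return regions[0]

    def test_discordant_site_splits(self):
        """HOM(A) vs HOM(G) at one interior site cuts the region in two."""
        p1 = "A" * 41
        p2 = "A" * 20 + "G" + "A" * 20
        m = make_matrix([p1, p2])
        region = self._one_region(m, ["S1", "S2"])
        segs = autozygosity_refine(region, m, ["S1", "S2"], min_run=15)
        assert [(s.start_idx, s.end_idx) for s in segs] == [(0, 19), (21, 40)]
        assert all(s.mode == "autozygous" for s in segs)

    def test_short_fragments_dropped(self):
        p1 = "A" * 30
        p2 = "A" * 10 + "G" + "A" * 19
        m = make_matrix([p1, p2])
        region = self._one_region(m, ["S1", "S2"])
        segs = autozygosity_refine(region, m, ["S1", "S2"], min_run=15)
        assert [(s.start_idx, s.end_idx) for s in segs] == [(11, 29)]

    def test_fully_concordant_region_unchanged(self):
        m = make_matrix(["A" * 25, "A" * 25])
        region = self._one_region(m, ["S1", "S2"])
        segs = autozygosity_refine(region, m, ["S1", "S2"], 15)
        assert len(segs) == 1
        assert (segs[0].start_idx, segs[0].end_idx) == (0, 24)
        assert segs[0].mode == "autozygous"

    def test_nocall_wildcard_preserves_concordance(self):
        p1 = "A" * 10 + "." + "A" * 10
        p2 = "A" * 10 + "G" + "A" * 10  # G only conflicts with a call, not '.'
        m = make_matrix([p1, p2])
        region = self._one_region(m, ["S1", "S2"])
        segs = autozygosity_refine(region, m, ["S1", "S2"], 15)
        assert [(s.start_idx, s.end_idx) for s in segs] == [(0, 20)]

    def test_requires_homozygous_mode_input(self):
        m = make_matrix(["A" * 20, "A" * 20])
        region = self._one_region(m, ["S1", "S2"])
        auto = autozygosity_refine(region, m, ["S1", "S2"], 15)[0]
        with pytest.raises(ValueError):
            autozygosity_refine(auto, m, ["S1", "S2"], 15)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_groupby_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_rows(rng, 3, 150, p_het=0.15, p_nocall=0.15)
        m = make_matrix(rows)
        min_run = 8
        patients = list(m.samples)
        codes = [list(m.row_codes(s)) for s in patients]
        masks = [oracle_inrun_mask(c, m.chrom_blocks, min_run) for c in codes]
        for region in shared_regions(m, patients, len(patients), min_run):
            expected = oracle_refine(region.start_idx, region.end_idx,
                                     codes, masks, region.chrom, min_run)
            got = autozygosity_refine(region, m, patients, min_run)
            assert [(s.chrom, s.start_idx, s.end_idx) for s in got] == expected

    @given(st.integers(0, 2 ** 31 - 1))
    def test_autozygous_contained_in_homozygous(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(random_rows(rng, 3, 120, p_het=0.2))
        cfg_h = AnalysisConfig(mode="homozygous", min_run=8)
        cfg_a = AnalysisConfig(mode="autozygous", min_run=8)
        homo = map_regions(m, list(m.samples), cfg_h)
        auto = map_regions(m, list(m.samples), cfg_a)
        for a in auto:
            assert any(h.chrom == a.chrom and h.start_idx <= a.start_idx
                       and a.end_idx <= h.end_idx for h in homo)

    def test_hemizygous_interval_detected_as_run(self):
        """Forcing an interval homozygous in all patients yields a region there."""
        rng = np.random.default_rng(3)
        rows = random_rows(rng, 2, 100, p_het=0.5, p_nocall=0.0)
        rows = [r[:40] + "A" * 20 + r[60:] for r in rows]
        m = make_matrix(rows)
        regions = shared_regions(m, m.samples, 2, 15)
        assert any(r.start_idx <= 40 and r.end_idx >= 59 for r in regions)


class TestRankRegions:
    def _region(self, chrom, start_bp, end_bp, n_markers):
        return SharedRegion(chrom=chrom, start_idx=0, end_idx=n_markers - 1,
                            start_bp=start_bp, end_bp=end_bp,
                            n_markers=n_markers, mode="homozygous",
                            supporting_patients=("S1",))

    def test_orders_by_bp_length(self):
        regs = [self._region("chr1", 1, 2_000_000, 50),
                self._region("chr2", 1, 5_000_000, 40),
                self._region("chr3", 1, 1_000_000, 60)]
        assert [r.chrom for r in rank_regions(regs)] == ["chr2", "chr1", "chr3"]

    def test_tie_breaks_by_marker_count(self):
        regs = [self._region("chr1", 1, 1000, 80),
                self._region("chr2", 1, 1000, 100)]
        assert [r.n_markers for r in rank_regions(regs)] == [100, 80]

    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 10 ** 6),
                              st.integers(1, 500)), max_size=20))
    def test_matches_sort_oracle(self, triples):
        regs = [self._region(f"chr{c}", 1, bp, n) for c, bp, n in triples]
        got = rank_regions(regs)
        expected = sorted(regs, key=lambda r: (-r.bp_length, -r.n_markers,
                                               r.chrom, r.start_bp))
        assert [(r.chrom, r.bp_length, r.n_markers) for r in got] == \
               [(r.chrom, r.bp_length, r.n_markers) for r in expected]
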