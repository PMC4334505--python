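"""SALI read processing: trimming, mapping, enrichment, merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnt1kit import sali, synthetic
from rnt1kit.core_io import GenomicInterval


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        assert sali.trim_adapter(["ACGTACGT" + "TTTTGGGG"], "ACGTACGT") == ["TTTTGGGG"]

    def test_read_without_adapter_unchanged(self):
        assert sali.trim_adapter(["TTTTGGGGCCCCAAAA"], "ACGTACGT") == ["TTTTGGGGCCCCAAAA"]

    def test_partial_adapter_suffix(self):
        # read starts mid-adapter: suffix "TACGT" of the adapter
        assert sali.trim_adapter(["TACGT" + "AAAACCCC"], "ACGTACGT") == ["AAAACCCC"]

    def test_mismatch_rate_boundary(self):
        adapter = "TGGAATTCTCGG"
        # one mismatch in the full 12-nt overlap; no shorter adapter suffix
        # matches the read prefix exactly
        read = "TGGAATTCTAGG" + "GGGGAAAA"
        assert sali.trim_adapter([read], adapter, max_error_rate=0.1) == ["GGGGAAAA"]
        assert sali.trim_adapter([read], adapter, max_error_rate=0.0) == [read]

    def test_brute_force_overlap_oracle(self):
        """Longest-prefix trimming equals a brute-force scan over all
        adapter-suffix overlaps."""
        rng = np.random.default_rng(3)
        adapter = "TGGAATTCTCGG"
        for _ in range(50):
            read = "".join(rng.choice(list("ACGT"), size=30))
            got = sali.trim_adapter([read], adapter, 0.1)[0]
            best = 0
            for k in range(min(len(adapter), len(read)), 2, -1):
                mism = sum(a != b for a, b in zip(adapter[-k:], read[:k]))
                if mism <= 0.1 * k:
                    best = k
                    break
            assert got == read[best:]

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            sali.trim_adapter(["ACGT"], "")


class TestFilterLengths:
    def test_threshold_boundary(self):
        reads = ["A" * 15, "A" * 16, "A" * 40]
        assert sali.filter_lengths(reads) == ["A" * 16, "A" * 40]

    def test_empty_input(self):
        assert sali.filter_lengths([]) == []

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 60), max_size=30))
    def test_count_preserved_minus_short(self, lengths):
        reads = ["A" * n for n in lengths]
        kept = sali.filter_lengths(reads)
        assert len(kept) == sum(1 for n in lengths if n >= 16)


class TestMapUnique:
    @pytest.fixture(scope="class")
    def genome(self):
        g, _ = synthetic.gen_genome(8000, seed=33)
        return g

    def test_single_match_placed_correctly(self, genome):
        seq = genome["chrS"]
        read = seq[1000:1035]
        placed, _, _ = sali.map_unique([read], genome)
        assert placed == [(read, GenomicInterval("chrS", 1000, 1035, "+"))]

    def test_reverse_strand_match(self, genome):
        from rnt1kit.motif import revcomp

        read = revcomp(genome["chrS"][2000:2035])
        placed, _, _ = sali.map_unique([read], genome)
        assert placed[0][1] == GenomicInterval("chrS", 2000, 2035, "-")

    def test_naive_search_oracle(self, genome):
        """Placements agree with a naive full-scan string search."""
        from rnt1kit.motif import revcomp

        seq = genome["chrS"]
        rng = np.random.default_rng(4)
        for _ in range(20):
            start = int(rng.integers(0, len(seq) - 35))
            read = seq[start : start + 35]
            naive = seq.count(read) + revcomp(seq).count(read)
            placed, _, _ = sali.map_unique([read], genome)
            assert (len(placed) == 1) == (naive == 1)

    def test_duplicated_read_discarded(self):
        g, _ = synthetic.gen_genome(4000, seed=34)
        seq = g["chrS"]
        dup = seq[500:535]
        g2 = {"chrS": seq[:3000] + dup + seq[3035:]}
        placed, discarded, _ = sali.map_unique([dup], g2)
        assert placed == [] and discarded == 1

    def test_length_window_boundaries(self, genome):
        seq = genome["chrS"]
        reads = [seq[100:131], seq[300:332], seq[600:638], seq[900:939]]
        placed, _, outside = sali.map_unique(reads, genome)
        assert sorted(len(r) for r, _ in placed) == [32, 38]
        assert outside == 2


class TestEnrichClusters:
    def _placed(self, seq, n, start=100):
        iv = GenomicInterval("chrS", start, start + len(seq), "+")
        return [(seq, iv)] * n

    def test_threshold_14(self):
        t = self._placed("A" * 35, 14)
        assert len(sali.enrich_clusters(t, [])) == 1
        t = self._placed("A" * 35, 13)
        assert sali.enrich_clusters(t, []) == []

    def test_any_control_count_blocks(self):
        t = self._placed("A" * 35, 100)
        c = self._placed("A" * 35, 1)
        assert sali.enrich_clusters(t, c) == []
        assert len(sali.enrich_clusters(t, c, max_control_count=1)) == 1


class TestMergeClusters:
    def _cluster(self, start, end, count=20, strand="+"):
        return sali.ReadCluster(
            sequence="A" * (end - start),
            interval=GenomicInterval("chrS", start, end, strand),
            count_treated=count,
            count_control=0,
        )

    def test_over_half_overlap_merges(self):
        merged = sali.merge_clusters([self._cluster(100, 135), self._cluster(110, 145)])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 145)

    def test_under_half_overlap_kept_separate(self):
        merged = sali.merge_clusters([self._cluster(100, 135), self._cluster(118, 153)])
        assert len(merged) == 2

    def test_disjoint_unchanged(self):
        merged = sali.merge_clusters([self._cluster(0, 35), self._cluster(500, 535)])
        assert len(merged) == 2

    def test_count_conservation_and_order_independence(self):
        clusters = [
            self._cluster(100, 135, 20),
            self._cluster(110, 145, 30),
            self._cluster(130, 165, 14),
            self._cluster(700, 735, 25),
        ]
        merged = sali.merge_clusters(clusters)
        assert sum(m.total_count for m in merged) == sum(c.count_treated for c in clusters)
        rev = sali.merge_clusters(clusters[::-1])
        assert sorted((m.interval.start, m.interval.end) for m in merged) == sorted(
            (m.interval.start, m.interval.end) for m in rev
        )

    def test_representative_is_longest(self):
        a = self._cluster(100, 135)
        b = sali.ReadCluster("G" * 38, GenomicInterval("chrS", 98, 136, "+"), 15, 0)
        merged = sali.merge_clusters([a, b])
        assert merged[0].representative == "G" * 38


class TestPipeline:
    def test_end_to_end_recovery_and_stage_monotonicity(self):
        genome, _ = synthetic.gen_genome(30_000, seed=35)
        sites = [
            (synthetic.CleavageSite(
                GenomicInterval("chrS", pos, pos + 35, "+"), 0.9, 200), copies)
            for pos, copies in [(5000, 20), (15000, 14), (25000, 13)]
        ]
        treated, control = synthetic.sim_sali(genome, sites, seed=36)
        merged, stats = sali.run_pipeline(
            treated, control, genome, synthetic.DEFAULT_ADAPTER
        )
        spans = {(m.interval.start, m.interval.end) for m in merged}
        assert (5000, 5035) in spans and (15000, 15035) in spans
        assert (25000, 25035) not in spans  # below the 14-copy threshold
        assert stats["treated_input"] >= stats["treated_after_length"] >= stats[
            "treated_placed_32_38"
        ]

    def test_background_only_zero_clusters(self):
        genome, _ = synthetic.gen_genome(20_000, seed=37)
        treated, control = synthetic.sim_sali(genome, [], seed=38)
        merged, _ = sali.run_pipeline(treated, control, genome, synthetic.DEFAULT_ADAPTER)
        assert merged == []
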