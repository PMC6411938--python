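import numpy as np
import pytest

from pitrimseq.alignment import AlignConfig, ReferenceIndex, align
from pitrimseq.distance_analysis import (
    cluster_pileup,
    distance_profile,
    select_reference_pirnas,
)
from pitrimseq.pipeline import RunConfig, process_library
from pitrimseq.preprocess import ClipConfig, clip_reads, filter_by_length
from pitrimseq.sequence_io import CollapsedRead, ReferenceSet, collapse_reads, revcomp


def random_seq(rng, length):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, length))


@pytest.fixture(scope="module")
def toy():
    """One 4 kb cluster with 20 well-separated planted reads on both strands."""
    rng = np.random.default_rng(83)
    cluster = random_seq(rng, 4000)
    refset = ReferenceSet(category="piRNA_cluster", records=[("chrP", cluster)], priority=1)
    reads = []
    for i in range(20):
        start = 100 + i * 190
        L = 26 + (i % 5)
        seq = cluster[start : start + L]
        if i % 2:
            seq = revcomp(seq)
        reads.append(CollapsedRead(id=f"w{i}", sequence=seq, count=20 - i))
    return refset, cluster, reads


class TestSelectReferences:
    def test_top_n_by_count_with_deterministic_ties(self, toy):
        refset, _, reads = toy
        refs = select_reference_pirnas(reads, refset, n=10)
        assert len(refs) == 10
        assert [r.count for r in refs] == sorted((r.count for r in refs), reverse=True)
        assert refs[0].count == 20 and refs[0].rank == 1

    def test_fewer_candidates_than_n_warns_and_returns_all(self, toy):
        refset, _, reads = toy
        with pytest.warns(UserWarning, match="only 20"):
            refs = select_reference_pirnas(reads, refset, n=10_000)
        assert len(refs) == 20

    def test_multi_mapping_sequence_is_excluded(self, toy):
        refset, cluster, reads = toy
        # plant a duplication: the first read's sequence occurs twice
        dup = reads[0].sequence
        dup_ref = ReferenceSet(
            category="piRNA_cluster",
            records=[("chrP", cluster), ("chrQ", random_seq(np.random.default_rng(5), 500) + dup)],
            priority=1,
        )
        refs = select_reference_pirnas(reads, dup_ref, n=20)
        assert all(r.sequence != dup for r in refs)
        # without the uniqueness rule the duplicated top read is kept
        loose = select_reference_pirnas(reads, dup_ref, n=20, unique_only=False)
        assert any(r.sequence == dup for r in loose)

    def test_no_candidates_is_an_error(self, toy):
        refset, *_ = toy
        stranger = [CollapsedRead(id="x", sequence="ACGT" * 7, count=1)]
        with pytest.raises(ValueError, match="no qualifying"):
            select_reference_pirnas(stranger, refset, n=5)


class TestDistanceProfile:
    def test_self_profile_is_a_point_mass_at_zero(self, toy):
        refset, _, reads = toy
        refs = select_reference_pirnas(reads, refset, n=20)
        for end in ("5p", "3p"):
            prof = distance_profile(refs, reads, refset, end=end)
            assert prof.frequency_at(0) == pytest.approx(1.0)
            assert prof.total == sum(r.count for r in reads)

    def test_constructed_plus_two_extension(self, toy):
        refset, cluster, reads = toy
        refs = select_reference_pirnas(reads, refset, n=20)
        by_seq = {r.sequence: r for r in refs}
        extended = []
        for i, r in enumerate(reads):
            ref = by_seq[r.sequence]
            if ref.strand == "+":
                seq = cluster[ref.anchor5 : ref.anchor3 + 2]
            else:
                seq = revcomp(cluster[ref.anchor3 - 2 : ref.anchor5])
            extended.append(CollapsedRead(id=f"e{i}", sequence=seq, count=r.count))
        p5 = distance_profile(refs, extended, refset, end="5p")
        p3 = distance_profile(refs, extended, refset, end="3p")
        assert p5.frequency_at(0) == pytest.approx(1.0)
        assert p3.frequency_at(2) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1, 5, 17])
    def test_translation_equivariance_of_3p_profile(self, toy, k):
        refset, cluster, reads = toy
        refs = select_reference_pirnas(reads, refset, n=20)
        by_seq = {r.sequence: r for r in refs}
        shifted = []
        for i, r in enumerate(reads):
            ref = by_seq[r.sequence]
            if ref.strand == "+":
                seq = cluster[ref.anchor5 : ref.anchor3 + k]
            else:
                seq = revcomp(cluster[ref.anchor3 - k : ref.anchor5])
            shifted.append(CollapsedRead(id=f"s{i}", sequence=seq, count=r.count))
        p3 = distance_profile(refs, shifted, refset, end="3p")
        assert p3.frequency_at(k) == pytest.approx(1.0)

    def test_minus_strand_extension_reports_positive_offset(self):
        """A minus-strand reference with a minus-strand extended query: the
        genomic shift is upstream, but the offset is downstream (+3)."""
        rng = np.random.default_rng(89)
        cluster = random_seq(rng, 300)
        refset = ReferenceSet("piRNA_cluster", [("chrM", cluster)], 1)
        mature = revcomp(cluster[100:128])
        wt = [CollapsedRead(id="w", sequence=mature, count=1)]
        refs = select_reference_pirnas(wt, refset, n=1)
        assert refs[0].strand == "-"
        query = [CollapsedRead(id="q", sequence=revcomp(cluster[97:128]), count=1)]
        p3 = distance_profile(refs, query, refset, end="3p")
        assert p3.frequency_at(3) == pytest.approx(1.0)
        assert p3.mass(-30, -1) == 0.0

    def test_empty_reference_list_fails(self, toy):
        refset, _, reads = toy
        with pytest.raises(ValueError, match="empty"):
            distance_profile([], reads, refset, end="5p")

    def test_zero_in_window_events_is_flagged(self, toy):
        refset, _, reads = toy
        refs = select_reference_pirnas(reads, refset, n=20)
        stranger = [CollapsedRead(id="x", sequence="ACGTACGT" * 4, count=1)]
        with pytest.warns(UserWarning, match="zero in-window"):
            prof = distance_profile(refs, stranger, refset, end="5p")
        assert prof.total == 0
        assert prof.frequencies.sum() == 0.0

    def test_frequencies_normalize_over_in_window_events(self, small_config, small_refs,
                                                         wt_small, mutant_small):
        cfg = RunConfig(simulation=small_config)
        wt = process_library("WT", wt_small[0], small_refs, cfg)
        mut = process_library("mutant", mutant_small[0], small_refs, cfg)
        index = ReferenceIndex(small_refs.sets["piRNA_cluster"])
        refs = select_reference_pirnas(wt.filtered, index, n=10_000)
        for end in ("5p", "3p"):
            prof = distance_profile(refs, mut.filtered, index, end=end)
            assert prof.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
            assert len(prof.offsets) == 61


class TestClusterPileup:
    def _alns(self, reads, refset):
        return align(reads, refset, AlignConfig(max_mismatch=0, report="all"))

    def test_length_class_boundaries_and_region(self, toy):
        refset, cluster, _ = toy
        reads = [
            CollapsedRead(id="short", sequence=cluster[500:530], count=1),  # 30 nt
            CollapsedRead(id="long", sequence=cluster[500:531], count=1),  # 31 nt
            CollapsedRead(id="outside", sequence=cluster[3000:3030], count=1),
        ]
        alns = self._alns(reads, refset)
        pileup = cluster_pileup(alns, alns, "chrP", (400, 1000))
        assert [a.read_id for a in pileup.track_a] == ["short"]
        assert [a.read_id for a in pileup.track_b] == ["long"]
        assert pileup.shared_5p_pairs == 1  # same 5' start, different class

    def test_unknown_cluster_id_fails(self, toy):
        refset, *_ = toy
        with pytest.raises(ValueError, match="unknown cluster"):
            cluster_pileup([], [], "chrZ", (0, 100), known_clusters={"chrP"})

    def test_shared_5p_pairs_match_truth(self, small_config, small_refs,
                                         wt_small, mutant_small):
        """Each extended mutant locus whose WT partner maps in the region
        contributes exactly one shared-5' anchor."""
        cfg = RunConfig(simulation=small_config)
        wt = process_library("WT", wt_small[0], small_refs, cfg)
        mut = process_library("mutant", mutant_small[0], small_refs, cfg)
        index = ReferenceIndex(small_refs.sets["piRNA_cluster"])
        perfect = AlignConfig(max_mismatch=0, report="all")
        cid = small_refs.sets["piRNA_cluster"].records[0][0]
        region = (0, small_config.cluster_length)
        pileup = cluster_pileup(
            align(wt.filtered, index, perfect),
            align(mut.filtered, index, perfect),
            cid,
            region,
            known_clusters=set(small_refs.cluster_seqs),
        )
        wt_truth = wt_small[1]
        mut_truth = mutant_small[1]

        def anchors(truth, reads, lo, hi):
            raw = dict(reads)
            out = set()
            for row in truth[truth["cluster_id"] == cid].itertuples():
                ins_len = len(raw[row.read_id]) - len(small_config.adapter)
                if lo <= ins_len <= hi:
                    out.add((row.g5, row.strand))
            return out

        expected = anchors(wt_truth, wt_small[0], 24, 30) & anchors(
            mut_truth, mutant_small[0], 31, 48
        )
        assert pileup.shared_5p_pairs == len(expected)
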