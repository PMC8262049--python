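import numpy as np
import pytest

from _oracles import expand_cigar_pairs
from poresig.errors import IdentityError, RangeError, SamplingError
from poresig.extract import extract_instances
from poresig.fast5 import index_fast5_dir, read_fast5
from poresig.sites import (ModificationSite, ReadAlignment, load_alignments,
                           read_sites, ref_to_read_pos, sample_control_sites,
                           site_kmer_signal)


def aln(cigar, ref_start=0, read_id="r", strand="+"):
    return ReadAlignment(read_id=read_id, ref_name="chrS",
                         ref_start=ref_start, cigar=tuple(cigar),
                         strand=strand)


class TestRefToReadPos:
    def test_pure_match_offset(self):
        a = aln([("M", 10)], ref_start=100)
        assert ref_to_read_pos(a, 104) == 4

    def test_deletion_returns_none(self):
        a = aln([("M", 5), ("D", 2), ("M", 5)])
        assert ref_to_read_pos(a, 6) is None
        assert ref_to_read_pos(a, 7) == 5  # first base after the deletion

    def test_insertion_shifts_read_positions(self):
        a = aln([("M", 5), ("I", 3), ("M", 5)])
        assert ref_to_read_pos(a, 4) == 4
        assert ref_to_read_pos(a, 5) == 8

    def test_soft_clip_offsets_read_positions(self):
        a = aln([("S", 4), ("M", 10)], ref_start=50)
        assert ref_to_read_pos(a, 50) == 4

    def test_outside_span_raises(self):
        a = aln([("M", 10)], ref_start=100)
        with pytest.raises(RangeError):
            ref_to_read_pos(a, 99)
        with pytest.raises(RangeError):
            ref_to_read_pos(a, 110)

    def test_agrees_with_expanded_pair_oracle_on_fuzzed_cigars(self):
        rng = np.random.default_rng(23)
        ops = ["M", "I", "D", "S", "N", "=", "X"]
        checked = 0
        for _ in range(500):
            n_elems = int(rng.integers(1, 8))
            cigar = []
            for k in range(n_elems):
                op = ops[int(rng.integers(0, len(ops)))]
                if k in (0, n_elems - 1) and op in "DN":
                    op = "M"  # alignments cannot start/end in a gap
                cigar.append((op, int(rng.integers(1, 12))))
            if not any(op in "M=X" for op, _ in cigar):
                cigar.append(("M", 5))
            ref_start = int(rng.integers(0, 1000))
            a = aln(cigar, ref_start=ref_start)
            mapping = expand_cigar_pairs(cigar, ref_start)
            for ref_pos in mapping:
                assert ref_to_read_pos(a, ref_pos) == mapping[ref_pos]
                checked += 1
        assert checked > 500


class TestSiteKmerSignal:
    def _read_and_aln(self, site_fixture, truth):
        fast5_dir, sam_path, _, _ = site_fixture
        index = index_fast5_dir(fast5_dir)
        read = read_fast5(index[truth["read_id"]])
        alignments = load_alignments(sam_path)
        return read, alignments[truth["read_id"]]

    def test_recovers_every_manifest_instance(self, site_fixture):
        fast5_dir, sam_path, bed_path, manifest = site_fixture
        sites = {s.site_id: s for s in read_sites(bed_path)}
        mappable = [t for t in manifest.site_truth if t["label"] == "mappable"]
        assert mappable
        for truth in mappable:
            read, alignment = self._read_and_aln(site_fixture, truth)
            inst = site_kmer_signal(sites[truth["site_id"]], alignment, read)
            assert inst is not None
            expected = extract_instances(read)[truth["event_index"]]
            assert inst.kmer == truth["kmer"] == expected.kmer
            np.testing.assert_array_equal(inst.values, expected.values)
            assert inst.label == truth["site_id"]
            # the modified/control base sits at the center of the 5-mer
            assert inst.kmer[2] == sites[truth["site_id"]].base

    def test_sites_in_deletions_and_near_edges_return_none(self, site_fixture):
        fast5_dir, sam_path, bed_path, manifest = site_fixture
        sites = {s.site_id: s for s in read_sites(bed_path)}
        unmappable = [t for t in manifest.site_truth
                      if t["label"] in ("in_deletion", "near_edge")]
        assert unmappable  # the generator placed at least one of each kind
        for truth in unmappable:
            read, alignment = self._read_and_aln(site_fixture, truth)
            assert site_kmer_signal(sites[truth["site_id"]],
                                    alignment, read) is None

    def test_read_alignment_identity_mismatch(self, site_fixture):
        fast5_dir, sam_path, bed_path, manifest = site_fixture
        truth = next(t for t in manifest.site_truth
                     if t["label"] == "mappable")
        read, _ = self._read_and_aln(site_fixture, truth)
        wrong = aln([("M", 60)], read_id="someone_else")
        site = ModificationSite("chrS", 10, "+", "A", "s")
        with pytest.raises(IdentityError):
            site_kmer_signal(site, wrong, read)

    def test_opposite_strand_site_not_matched(self, site_fixture):
        fast5_dir, sam_path, bed_path, manifest = site_fixture
        truth = next(t for t in manifest.site_truth
                     if t["label"] == "mappable")
        sites = {s.site_id: s for s in read_sites(bed_path)}
        site = sites[truth["site_id"]]
        minus_site = ModificationSite(site.chrom, site.position, "-",
                                      site.base, site.site_id)
        read, alignment = self._read_and_aln(site_fixture, truth)
        assert site_kmer_signal(minus_site, alignment, read) is None


class TestSampleControlSites:
    @staticmethod
    def _getter(seq):
        return lambda chrom, pos: seq[pos]

    def test_exhaustive_eligible_set(self):
        seq = "AATTAGGGTA"  # A at 0,1,4,9
        sites = sample_control_sites([("chrS", 0, 10)], "A", 4,
                                     self._getter(seq), seed=0)
        assert sorted(s.position for s in sites) == [0, 1, 4, 9]
        assert all(s.base == "A" for s in sites)

    def test_exclusion_set_can_exhaust_candidates(self):
        seq = "AATTAGGGTA"
        exclude = {("chrS", p) for p in (0, 1, 4, 9)}
        with pytest.raises(SamplingError, match="0 eligible"):
            sample_control_sites([("chrS", 0, 10)], "A", 1,
                                 self._getter(seq), seed=0, exclude=exclude)

    def test_seeded_samples_reproducible_and_base_matched(self):
        rng = np.random.default_rng(24)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        regions = [("chrS", 0, 2000)]
        a = sample_control_sites(regions, "C", 100, self._getter(seq), seed=1)
        a2 = sample_control_sites(regions, "C", 100, self._getter(seq), seed=1)
        b = sample_control_sites(regions, "C", 100, self._getter(seq), seed=2)
        assert [s.position for s in a] == [s.position for s in a2]
        assert all(seq[s.position] == "C" for s in a + b)
        # two independent draws of 100 from ~500 C positions: overlap stays
        # inside the simulated hypergeometric 99% band
        n_c = seq.count("C")
        overlap = len({s.position for s in a} & {s.position for s in b})
        sims = []
        sim_rng = np.random.default_rng(0)
        for _ in range(2000):
            x = set(sim_rng.choice(n_c, 100, replace=False))
            y = set(sim_rng.choice(n_c, 100, replace=False))
            sims.append(len(x & y))
        lo, hi = np.quantile(sims, [0.005, 0.995])
        assert lo <= overlap <= hi


def test_label_partition_of_modified_and_control_extractions(site_fixture):
    from poresig.sites import extract_site_instances

    fast5_dir, sam_path, bed_path, manifest = site_fixture
    index = index_fast5_dir(fast5_dir)
    reads = {rid: read_fast5(p) for rid, p in index.items()}
    alignments = load_alignments(sam_path)
    sites = read_sites(bed_path)
    half = len(sites) // 2
    modified = extract_site_instances(sites[:half], alignments, reads,
                                      label="modified")
    control = extract_site_instances(sites[half:], alignments, reads,
                                     label="control")
    assert {i.label for i in modified} <= {"modified"}
    assert {i.label for i in control} <= {"control"}
    assert not ({i.instance_id for i in modified}
                & {i.instance_id for i in control})
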