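"""Homopolymer segmentation, offset matrix, masking and k-mer tables."""
import numpy as np
import pysam
import pytest

import _walker
from avitool.profiles import (
    HomopolymerInterval,
    SiteMask,
    compare_platforms,
    filter_reads,
    FilterStats,
    homopolymer_error_summary,
    kmer_mismatch_table,
    load_homopolymer_bed,
    mask_known_sites,
    segment_read,
)
from avitool.simulate.fixture import (
    generate_profiling_fixture,
    generate_uniform_error_fixture,
)


def _make_sam(path, reference, records, contig="sim1"):
    """Write a SAM with arbitrary CIGARs for oracle comparisons."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": contig, "LN": len(reference[contig])}]}
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, flag, pos, mapq, cigar, seq in sorted(records, key=lambda r: r[2]):
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.reference_id = 0 if not flag & 4 else -1
            a.reference_start = pos if not flag & 4 else -1
            if not flag & 4:
                a.cigarstring = cigar
            a.mapping_quality = mapq
            out.write(a)


def _reads(path):
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        yield from af.fetch(until_eof=True)


class TestBedLoading:
    def test_slop_trim_arithmetic(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t95\t125\thp0\n")
        ivs = load_homopolymer_bed(bed, slop=5)
        assert (ivs[0].start, ivs[0].end, ivs[0].length) == (100, 120, 20)

    def test_zero_slop_is_identity(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t100\t120\thp0\n")
        ivs = load_homopolymer_bed(bed, slop=0)
        assert (ivs[0].start, ivs[0].end) == (100, 120)

    def test_empty_after_trim_rejected(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t100\t108\thp0\nchr1\t200\t230\thp1\n")
        ivs = load_homopolymer_bed(bed, slop=5)
        assert len(ivs) == 1 and ivs[0].start == 205

    def test_fixture_bed_validates_against_reference(self, tmp_path):
        fx = generate_profiling_fixture(
            seed=3, homopolymer_spec=[("A", 15, 500), ("G", 20, 1500)],
            n_reads=4, out_dir=tmp_path)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        assert [iv.base for iv in ivs] == ["A", "G"]
        assert [iv.length for iv in ivs] == [15, 20]


class TestFilterReads:
    def test_exact_flag_and_mapq_rules(self, tmp_path):
        fx = generate_profiling_fixture(seed=4, n_reads=10, out_dir=tmp_path)
        stats = FilterStats()
        kept = list(filter_reads(_reads(fx.sam_path), stats))
        assert len(kept) == 10
        assert stats.secondary == stats.supplementary == 1
        assert stats.unmapped == stats.mapq_zero == 1
        assert all(r.mapping_quality > 0 for r in kept)


class TestSegmentRead:
    def _worked_example(self, tmp_path, reverse=False):
        """150-bp read with a homopolymer overlapping read positions 100-120
        (1-based): pre = 99 aligned bases, overlap = 21, post = 30."""
        rng = np.random.default_rng(0)
        bases = "ACGT"
        ref = [bases[i] for i in rng.integers(0, 4, 400)]
        hp_start, hp_end = 199, 220  # read starts at 100 -> read offsets 99..119
        ref[hp_start:hp_end] = "A" * 21
        ref[hp_start - 1] = "C"
        ref[hp_end] = "C"
        reference = {"sim1": "".join(ref)}
        start = 100
        seq = reference["sim1"][start : start + 150]
        sam = tmp_path / "we.sam"
        flag = 16 if reverse else 0
        _make_sam(sam, reference, [("r0", flag, start, 60, "150M", seq)])
        read = next(_reads(sam))
        iv = HomopolymerInterval("sim1", hp_start, hp_end, base="A")
        return segment_read(read, iv, reference)

    def test_worked_example_forward(self, tmp_path):
        seg = self._worked_example(tmp_path)
        assert seg.pre_aligned == 99
        assert seg.overlap_aligned == 21
        assert seg.post_aligned == 30
        assert seg.pre_range == (0, 99)
        assert seg.post_range == (120, 150)

    def test_worked_example_reverse_swaps_ends(self, tmp_path):
        seg = self._worked_example(tmp_path, reverse=True)
        # same genomic geometry; in read orientation the segments swap
        assert seg.pre_aligned == 30
        assert seg.post_aligned == 99
        assert seg.overlap_aligned == 21

    def test_short_flank_discarded(self, tmp_path):
        reference = {"sim1": "C" * 50 + "A" * 15 + "G" * 50}
        iv = HomopolymerInterval("sim1", 50, 65, base="A")
        # read covering the run with a 4-base post flank
        start, length = 30, 50 - 30 + 15 + 4
        seq = reference["sim1"][start : start + length]
        sam = tmp_path / "s.sam"
        _make_sam(sam, reference, [("r0", 0, start, 60, f"{length}M", seq)])
        assert segment_read(next(_reads(sam)), iv, reference) is None

    def test_read_inside_interval_discarded(self, tmp_path):
        reference = {"sim1": "C" * 20 + "A" * 40 + "G" * 20}
        iv = HomopolymerInterval("sim1", 20, 60, base="A")
        seq = reference["sim1"][25:55]
        sam = tmp_path / "s.sam"
        _make_sam(sam, reference, [("r0", 0, 25, 60, "30M", seq)])
        assert segment_read(next(_reads(sam)), iv, reference) is None

    def test_segment_additivity_with_indels_and_clips(self, tmp_path):
        """pre+overlap+post aligned bases equal all matched, non-clip,
        non-indel, non-N columns of the read."""
        rng = np.random.default_rng(1)
        ref = [c for c in "ACGT" * 100]
        ref[150:170] = "A" * 20
        ref[149] = "C"
        ref[170] = "C"
        reference = {"sim1": "".join(ref)}
        # 10S 60M 2I 30M 3D 40M: starts at 60, matched = 130 columns
        r = reference["sim1"]
        seq = ("T" * 10) + r[60:120] + "GG" + r[120:150] + r[153:193]
        sam = tmp_path / "s.sam"
        _make_sam(sam, reference, [("r0", 0, 60, 60, "10S60M2I30M3D40M", seq)])
        read = next(_reads(sam))
        iv = HomopolymerInterval("sim1", 150, 170, base="A")
        seg = segment_read(read, iv, reference)
        assert seg.total_aligned == 130
        counts = _walker.segment_counts(
            next(_walker.parse_sam(sam)), reference, 150, 170)
        assert (seg.pre_aligned, seg.pre_mismatch) == tuple(counts["pre"])
        assert (seg.overlap_aligned, seg.overlap_mismatch) == tuple(counts["overlap"])
        assert (seg.post_aligned, seg.post_mismatch) == tuple(counts["post"])


class TestSummary:
    def test_error_free_fixture_reports_zero(self, tmp_path):
        fx = generate_profiling_fixture(
            seed=5, homopolymer_spec=[("A", 15, 1000)], pre_error=0.0,
            post_error=0.0, n_reads=50, out_dir=tmp_path)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        s = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        assert s.pre_mismatch == 0 and s.post_mismatch == 0
        assert s.n_reads_used == 50

    def test_counts_match_brute_force_walker(self, tmp_path):
        """On a <=50-read fixture every count equals the independent walker."""
        fx = generate_profiling_fixture(
            seed=6, homopolymer_spec=[("T", 14, 800)], pre_error=0.02,
            post_error=0.08, n_reads=50, out_dir=tmp_path, reverse_fraction=0.4)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        s = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        totals = {"pre": [0, 0], "overlap": [0, 0], "post": [0, 0]}
        for rec in _walker.parse_sam(fx.sam_path):
            if not _walker.keep(rec):
                continue
            c = _walker.segment_counts(rec, fx.reference, 800, 814)
            if c["pre"][0] < 5 or c["post"][0] < 5 or c["overlap"][0] == 0:
                continue
            for k in totals:
                totals[k][0] += c[k][0]
                totals[k][1] += c[k][1]
        assert (s.pre_aligned, s.pre_mismatch) == tuple(totals["pre"])
        assert (s.overlap_aligned, s.overlap_mismatch) == tuple(totals["overlap"])
        assert (s.post_aligned, s.post_mismatch) == tuple(totals["post"])

    def test_injected_rates_recovered_within_binomial_ci(self, tmp_path):
        from scipy import stats

        fx = generate_profiling_fixture(
            seed=7, homopolymer_spec=[("A", 15, 1000)], pre_error=0.001,
            post_error=0.005, n_reads=5000, out_dir=tmp_path)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        s = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        for rate, n, k in ((0.001, s.pre_aligned, s.pre_mismatch),
                           (0.005, s.post_aligned, s.post_mismatch)):
            lo, hi = stats.binom.interval(0.999, n, rate)
            assert lo <= k <= hi

    def test_elevated_post_regime_ratio(self, tmp_path):
        """A 5x post/pre error fixture yields a ~5x rate ratio."""
        fx = generate_profiling_fixture(
            seed=8, homopolymer_spec=[("G", 20, 1000)], pre_error=0.004,
            post_error=0.02, n_reads=4000, out_dir=tmp_path)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        s = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        assert s.post_rate / s.pre_rate == pytest.approx(5.0, rel=0.3)

    def test_flat_regime_difference_near_zero(self, tmp_path):
        fx = generate_profiling_fixture(
            seed=9, homopolymer_spec=[("A", 15, 1000)], pre_error=0.005,
            post_error=0.005, n_reads=4000, out_dir=tmp_path)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        s = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        assert abs(s.post_rate - s.pre_rate) < 0.002

    def test_offset_matrix_conserves_aligned_bases(self, tmp_path):
        fx = generate_profiling_fixture(
            seed=10, homopolymer_spec=[("A", 15, 1000)], pre_error=0.01,
            post_error=0.03, n_reads=300, out_dir=tmp_path)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        s = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        m = s.offset_matrix
        pre_total = m.loc[m["offset"] < 0, "aligned"].sum()
        post_total = m.loc[m["offset"] >= 0, "aligned"].sum()
        assert pre_total == s.pre_aligned
        assert post_total == s.post_aligned
        assert (m["mismatch"] <= m["aligned"]).all()

    def test_orientation_involution(self, tmp_path):
        """Profiling the reverse-complemented mirror of a fixture yields
        identical segment summaries."""
        fx = generate_profiling_fixture(
            seed=11, homopolymer_spec=[("A", 15, 900)], pre_error=0.01,
            post_error=0.04, n_reads=200, out_dir=tmp_path / "fwd",
            reverse_fraction=0.3, include_decoys=False)
        ref = fx.reference["sim1"]
        L = len(ref)
        comp = str.maketrans("ACGT", "TGCA")
        mirror_ref = {"sim1": ref.translate(comp)[::-1]}
        records = []
        for rec in _walker.parse_sam(fx.sam_path):
            end = rec["pos"] + len(rec["seq"])
            records.append((
                rec["qname"], rec["flag"] ^ 16, L - end, rec["mapq"],
                rec["cigar"], rec["seq"].translate(comp)[::-1],
            ))
        sam2 = tmp_path / "mirror.sam"
        _make_sam(sam2, mirror_ref, records)
        iv = fx.intervals[0]
        iv2 = HomopolymerInterval("sim1", L - iv.end, L - iv.start, base="T")
        s1 = homopolymer_error_summary(str(fx.sam_path), fx.intervals, fx.reference)
        s2 = homopolymer_error_summary(str(sam2), [iv2], mirror_ref)
        assert (s1.pre_aligned, s1.pre_mismatch) == (s2.pre_aligned, s2.pre_mismatch)
        assert (s1.post_aligned, s1.post_mismatch) == (s2.post_aligned, s2.post_mismatch)
        assert (s1.overlap_aligned, s1.overlap_mismatch) == \
            (s2.overlap_aligned, s2.overlap_mismatch)


class TestMasking:
    def test_masked_snp_contributes_nothing(self, tmp_path):
        fx = generate_profiling_fixture(
            seed=12, homopolymer_spec=[("A", 15, 1000)], pre_error=0.0,
            post_error=0.0, n_reads=100, out_dir=tmp_path,
            snp_positions=[960, 1050])
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        unmasked = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        assert unmasked.pre_mismatch + unmasked.post_mismatch > 0
        masked = mask_known_sites(
            fx.reference, [("sim1", p, p + 1) for p in fx.snp_positions])
        s = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference,
                                      mask=masked.mask)
        assert s.pre_mismatch == 0 and s.post_mismatch == 0
        # denominators drop by exactly the masked columns
        snp_cols = unmasked.pre_aligned - s.pre_aligned + \
            unmasked.post_aligned - s.post_aligned
        assert snp_cols > 0

    def test_empty_mask_is_identity(self, tmp_path):
        fx = generate_profiling_fixture(seed=13, n_reads=20, out_dir=tmp_path)
        ivs = load_homopolymer_bed(fx.bed_path, slop=5, reference=fx.reference)
        a = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference)
        b = homopolymer_error_summary(str(fx.sam_path), ivs, fx.reference,
                                      mask=SiteMask(fx.reference))
        assert (a.pre_aligned, a.post_aligned) == (b.pre_aligned, b.post_aligned)

    def test_out_of_bounds_mask_rejected(self):
        ref = {"sim1": "ACGT" * 10}
        with pytest.raises(ValueError, match="bounds"):
            mask_known_sites(ref, [("sim1", 39, 45)])

    def test_vcf_mask_loading(self, tmp_path):
        ref = {"sim1": "ACGTACGTAC"}
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=sim1,length=10>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "sim1\t3\t.\tG\tA\t.\t.\t.\n"
        )
        masked = mask_known_sites(ref, vcf)
        assert masked.mask.is_masked("sim1", np.array([2]))[0]
        assert not masked.mask.is_masked("sim1", np.array([1, 3])).any()


class TestKmerTable:
    def test_enumerates_all_contexts(self, tmp_path):
        fx = generate_uniform_error_fixture(seed=14, n_reads=5, out_dir=tmp_path)
        for k, rows in ((1, 4), (2, 16), (3, 64)):
            t = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=k)
            assert len(t.table) == rows

    def test_error_free_fixture_all_zero(self, tmp_path):
        fx = generate_uniform_error_fixture(seed=15, n_reads=50, error_rate=0.0,
                                            out_dir=tmp_path)
        t = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=2)
        assert t.table["mismatching"].sum() == 0

    def test_uniform_error_closed_form(self, tmp_path):
        """Uniform per-base error e gives instance mismatch fraction
        1-(1-e)^k within the binomial interval."""
        from scipy import stats

        e = 0.01
        fx = generate_uniform_error_fixture(seed=16, n_reads=800, error_rate=e,
                                            ref_length=3000, out_dir=tmp_path)
        t = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=2)
        n = int(t.table["instances"].sum())
        bad = int(t.table["mismatching"].sum())
        p = 1 - (1 - e) ** 2
        lo, hi = stats.binom.interval(0.999, n, p)
        # windows overlap so instances are correlated; widen by 2x the band
        half = (hi - lo) / 2
        assert abs(bad - n * p) <= 2 * half

    def test_counts_match_brute_force_walker(self, tmp_path):
        fx = generate_profiling_fixture(
            seed=17, homopolymer_spec=[("A", 13, 700)], pre_error=0.05,
            post_error=0.05, n_reads=30, out_dir=tmp_path, reverse_fraction=0.5)
        for k in (1, 2, 3):
            t = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=k)
            oracle = _walker.kmer_counts(
                _walker.parse_sam(fx.sam_path), fx.reference, k)
            for _, row in t.table.iterrows():
                inst, mm = oracle.get(row["kmer"], (0, 0))
                assert (row["instances"], row["mismatching"]) == (inst, mm), row["kmer"]

    def test_masked_positions_excluded_from_instances(self, tmp_path):
        fx = generate_uniform_error_fixture(seed=18, n_reads=40, error_rate=0.0,
                                            out_dir=tmp_path)
        masked = mask_known_sites(fx.reference, [("sim1", 100, 200)])
        a = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=1)
        b = kmer_mismatch_table(str(fx.sam_path), masked, k=1)
        assert b.table["instances"].sum() < a.table["instances"].sum()

    def test_invalid_k_rejected(self, tmp_path):
        fx = generate_uniform_error_fixture(seed=19, n_reads=2, out_dir=tmp_path)
        with pytest.raises(ValueError, match="k must be"):
            kmer_mismatch_table(str(fx.sam_path), fx.reference, k=4)

    def test_sample_fraction_subsamples_reads(self, tmp_path):
        fx = generate_uniform_error_fixture(seed=20, n_reads=400, out_dir=tmp_path)
        full = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=1)
        sub = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=1,
                                  sample_fraction=0.25, seed=1)
        ratio = sub.table["instances"].sum() / full.table["instances"].sum()
        assert 0.15 < ratio < 0.35
        again = kmer_mismatch_table(str(fx.sam_path), fx.reference, k=1,
                                    sample_fraction=0.25, seed=1)
        assert (again.table["instances"] == sub.table["instances"]).all()


class TestComparePlatforms:
    def _table(self, fx_path, ref, k=1, **kw):
        return kmer_mismatch_table(str(fx_path), ref, k=k, **kw)

    def test_identical_tables_all_tie(self, tmp_path):
        fx = generate_uniform_error_fixture(seed=21, n_reads=50, error_rate=0.01,
                                            out_dir=tmp_path)
        t = self._table(fx.sam_path, fx.reference)
        res = compare_platforms([t, t])
        assert res["wins"] == 0 and res["ties"] == 4

    def test_planted_ordering(self):
        import pandas as pd

        from avitool.profiles import KmerMismatchTable, _all_kmers

        kmers = _all_kmers(1)

        def make(pcts):
            return KmerMismatchTable(k=1, table=pd.DataFrame(
                {"kmer": kmers, "instances": 1000,
                 "mismatching": [int(10 * p) for p in pcts], "pct": pcts}))

        best = make([0.1, 0.1, 0.1, 0.1])
        mid = make([0.2, 0.2, 0.1, 0.3])
        worst = make([0.3, 0.3, 0.3, 0.3])
        res = compare_platforms([best, mid, worst])
        assert res["wins"] == 3 and res["ties"] == 1 and res["losses"] == 0

    def test_mismatched_row_sets_rejected(self):
        import pandas as pd

        from avitool.profiles import KmerMismatchTable

        a = KmerMismatchTable(k=1, table=pd.DataFrame(
            {"kmer": list("ACGT"), "instances": 1, "mismatching": 0, "pct": 0.0}))
        b = KmerMismatchTable(k=2, table=pd.DataFrame(
            {"kmer": ["AA"], "instances": 1, "mismatching": 0, "pct": 0.0}))
        with pytest.raises(ValueError):
            compare_platforms([a, b])
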