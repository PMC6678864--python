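"""Re-pairing, orientation, size formulas, classification, dedup, dangling."""

import numpy as np
import pysam
import pytest

from capqc.digestmap import DigestMap
from capqc.pairclass import (
    Category,
    MappedRead,
    Orientation,
    ReadPair,
    Thresholds,
    classify,
    classify_pairs,
    deduplicate,
    fragment_size_lr,
    is_dangling,
    orientation,
    re_pair,
    segment_size,
    selfligation_size_ls,
    unligated_size_lu,
)

from conftest import make_map, mk_pair

THRESH = Thresholds()  # 1000 / 3000 / [50, 1000] / mapq 30


@pytest.fixture
def dmap():
    # chr1 digests: (1,100) (101,400) (401,800) (801,1200) (1201,2000)
    #               (2001,8000) (8001,20000); chr2: (1,1000) (1001,5000)
    return make_map({
        "chr1": [100, 400, 800, 1200, 2000, 8000, 20000],
        "chr2": [1000, 5000],
    })


class TestOrientation:
    def test_inward(self):
        p = mk_pair("chr1", 100, "+", "chr1", 500, "-")
        assert orientation(p) is Orientation.INWARD

    def test_outward(self):
        p = mk_pair("chr1", 600, "+", "chr1", 300, "-")
        assert orientation(p) is Orientation.OUTWARD

    def test_right_and_left(self):
        assert orientation(mk_pair("chr1", 100, "+", "chr1", 900, "+")) is Orientation.RIGHT
        assert orientation(mk_pair("chr1", 100, "-", "chr1", 900, "-")) is Orientation.LEFT

    def test_equal_positions_tie_breaks_inward(self):
        p = mk_pair("chr1", 300, "+", "chr1", 300, "-")
        assert orientation(p) is Orientation.INWARD

    def test_invariant_under_file_swap(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            fp1, fp2 = rng.integers(1, 1000, size=2)
            s1, s2 = rng.choice(["+", "-"], size=2)
            a = mk_pair("chr1", int(fp1), s1, "chr1", int(fp2), s2)
            b = mk_pair("chr1", int(fp2), s2, "chr1", int(fp1), s1)
            assert orientation(a) is orientation(b)

    def test_trans_pair_rejected(self):
        with pytest.raises(ValueError, match="trans"):
            orientation(mk_pair("chr1", 1, "+", "chr2", 1, "-"))


class TestSizes:
    def test_segment_size_forward(self, dmap):
        read = MappedRead("r", "chr1", 150, "+")
        assert segment_size(read, dmap) == 251  # digest (101,400): 400-150+1

    def test_segment_size_reverse(self, dmap):
        read = MappedRead("r", "chr1", 980, "-")
        assert segment_size(read, dmap) == 180  # digest (801,1200): 980-801+1

    def test_segment_size_at_cut_site_is_full_digest(self, dmap):
        read = MappedRead("r", "chr1", 101, "+")
        assert segment_size(read, dmap) == 300

    def test_lr_sums_segments(self, dmap):
        p = mk_pair("chr1", 150, "+", "chr1", 980, "-")
        assert fragment_size_lr(p, dmap) == 251 + 180

    def test_lr_outward_within_digest(self, dmap):
        p = mk_pair("chr1", 1500, "+", "chr1", 1200 + 1, "-")  # digest (1201,2000)
        # fwd 5'=1500 -> 2000-1500+1=501 ; rev 5'=1201 -> 1201-1201+1=1
        assert fragment_size_lr(p, dmap) == 502

    def test_lr_defined_for_trans(self, dmap):
        p = mk_pair("chr1", 150, "+", "chr2", 500, "-")
        assert fragment_size_lr(p, dmap) == 251 + 500

    def test_lu_inward_inclusive_span(self):
        p = mk_pair("chr1", 1100, "+", "chr1", 1400, "-")
        assert unligated_size_lu(p) == 301

    def test_lu_outward_gap(self):
        p = mk_pair("chr1", 1500, "+", "chr1", 1200, "-")
        assert unligated_size_lu(p) == 299

    def test_lu_same_position_inward_is_one(self):
        p = mk_pair("chr1", 700, "+", "chr1", 700, "-")
        assert unligated_size_lu(p) == 1

    def test_lu_undefined_same_strand(self):
        with pytest.raises(ValueError):
            unligated_size_lu(mk_pair("chr1", 1, "+", "chr1", 9, "+"))

    def test_ls_equals_lu_plus_lr(self, dmap):
        p = mk_pair("chr1", 1500, "+", "chr1", 1200, "-")
        # within digest (1201,2000): lu=299, lr=501+... rev 5'=1200 is in
        # digest (801,1200): spans two digests
        assert selfligation_size_ls(p, dmap) == unligated_size_lu(p) + fragment_size_lr(p, dmap)

    def test_ls_within_one_digest_equals_digest_length(self, dmap):
        # outward pair wholly inside digest (1201,2000), length 800
        p = mk_pair("chr1", 1500, "+", "chr1", 1250, "-")
        assert selfligation_size_ls(p, dmap) == 800

    def test_ls_spanning_adjacent_digests(self, dmap):
        # rev mate in (801,1200), fwd mate in (1201,2000): ls equals the
        # distance between the flanking restriction sites = 800+1200-800 ...
        # brute force: lu + lr where lr runs to the two outer boundaries
        p = mk_pair("chr1", 1500, "+", "chr1", 1000, "-")
        lu = 1500 - 1000 - 1
        lr = (2000 - 1500 + 1) + (1000 - 801 + 1)
        assert selfligation_size_ls(p, dmap) == lu + lr == 2000 - 801 + 1

    def test_ls_randomized_closed_form(self, dmap):
        rng = np.random.default_rng(21)
        d = dmap.lookup("chr1", 2001)  # digest (2001,8000), length 6000
        for _ in range(1000):
            a, b = sorted(rng.integers(d.start, d.end + 1, size=2))
            p = mk_pair("chr1", int(b), "+", "chr1", int(a), "-")
            if orientation(p) is not Orientation.OUTWARD:
                continue
            assert selfligation_size_ls(p, dmap) == d.length


class TestClassify:
    def test_inward_same_digest_unligated(self, dmap):
        p = mk_pair("chr1", 1250, "+", "chr1", 1900, "-")
        assert classify(p, dmap, THRESH) is Category.UNLIGATED

    def test_outward_same_digest_self_ligated(self, dmap):
        p = mk_pair("chr1", 1900, "+", "chr1", 1250, "-")
        assert classify(p, dmap, THRESH) is Category.SELF_LIGATED

    def test_same_strand_same_digest_strange_internal(self, dmap):
        p = mk_pair("chr1", 1250, "+", "chr1", 1900, "+")
        assert classify(p, dmap, THRESH) is Category.STRANGE_INTERNAL

    def test_trans_valid_size(self, dmap):
        p = mk_pair("chr1", 8000 - 299, "+", "chr2", 400, "-")  # segments 300+400
        assert classify(p, dmap, THRESH) is Category.VALID
        assert p.is_cis is False and p.lr == 700

    def test_inward_adjacent_digests_small_lu_unligated(self, dmap):
        # spans boundary at 1200: fwd in (801,1200), rev in (1201,2000)
        p = mk_pair("chr1", 1150, "+", "chr1", 1450, "-")
        assert unligated_size_lu(p) == 301 <= THRESH.max_unligated_size
        assert classify(p, dmap, THRESH) is Category.UNLIGATED

    def test_outward_adjacent_digests_small_ls_self_ligated(self, dmap):
        p = mk_pair("chr1", 1500, "+", "chr1", 1000, "-")
        assert selfligation_size_ls(p, dmap) == 1200 <= THRESH.max_selfligation_size
        assert classify(p, dmap, THRESH) is Category.SELF_LIGATED

    def test_cis_inward_large_lu_chimeric_too_long(self, dmap):
        # fwd at 101 (segment 300), rev at 8000-1130 (segment far into digest)
        p = mk_pair("chr1", 101, "+", "chr1", 3131, "-")
        assert classify(p, dmap, THRESH) is Category.CHIMERIC_TOO_LONG
        assert p.lr == 300 + (3131 - 2001 + 1)

    def test_cis_same_strand_different_digests_chimeric(self, dmap):
        p = mk_pair("chr1", 350, "+", "chr1", 3500, "+")
        # lr = (400-350+1) + (8000-3500+1): way over valid max
        assert classify(p, dmap, THRESH) is Category.CHIMERIC_TOO_LONG

    def test_too_short(self, dmap):
        p = mk_pair("chr1", 395, "+", "chr2", 4990, "+")
        # segments (400-395+1)=6 + (5000-4990+1)=11 -> lr=17 < 50
        assert classify(p, dmap, THRESH) is Category.CHIMERIC_TOO_SHORT

    def test_unmapped_input_rejected(self, dmap):
        p = ReadPair(
            MappedRead("r", None, 0, "+", is_unmapped=True),
            MappedRead("r", "chr1", 5, "+"),
        )
        with pytest.raises(ValueError, match="mapping filters"):
            classify(p, dmap, THRESH)


def oracle_classify(pair, dmap, th):
    """Independent nested-conditional re-derivation of the decision tree."""
    f, r = pair.fwd, pair.rev
    d_f = dmap.lookup(f.chrom, f.five_prime)
    d_r = dmap.lookup(r.chrom, r.five_prime)
    seg_f = d_f.end - f.five_prime + 1 if f.strand == "+" else f.five_prime - d_f.start + 1
    seg_r = d_r.end - r.five_prime + 1 if r.strand == "+" else r.five_prime - d_r.start + 1
    lr = seg_f + seg_r

    def size_filter():
        if lr < th.valid_size_min:
            return Category.CHIMERIC_TOO_SHORT
        if lr > th.valid_size_max:
            return Category.CHIMERIC_TOO_LONG
        return Category.VALID

    if f.chrom != r.chrom:
        return size_filter()
    same_digest = (d_f.start, d_f.end) == (d_r.start, d_r.end)
    if f.strand == r.strand:
        return Category.STRANGE_INTERNAL if same_digest else size_filter()
    plus, minus = (f, r) if f.strand == "+" else (r, f)
    inward = plus.five_prime <= minus.five_prime
    span = abs(f.five_prime - r.five_prime)
    if inward:
        if same_digest or span + 1 <= th.max_unligated_size:
            return Category.UNLIGATED
        return size_filter()
    if same_digest or (span - 1) + lr <= th.max_selfligation_size:
        return Category.SELF_LIGATED
    return size_filter()


class TestOracleEquivalence:
    def test_production_matches_brute_force_tree(self, dmap):
        rng = np.random.default_rng(99)
        chroms = dmap.chromosomes
        lengths = {c: dmap.chromosome_length(c) for c in chroms}
        for _ in range(2000):
            c1, c2 = rng.choice(chroms, size=2)
            p = mk_pair(
                c1, int(rng.integers(1, lengths[c1] + 1)), str(rng.choice(["+", "-"])),
                c2, int(rng.integers(1, lengths[c2] + 1)), str(rng.choice(["+", "-"])),
            )
            assert classify(p, dmap, THRESH) is oracle_classify(p, dmap, THRESH)


class TestDeduplicate:
    def test_identical_pairs_collapse(self):
        a = mk_pair("chr1", 100, "+", "chr1", 500, "-", name="a")
        b = mk_pair("chr1", 100, "+", "chr1", 500, "-", name="b")
        kept, dupes = deduplicate([a, b])
        assert [p.name for p in kept] == ["a"] and dupes == 1

    def test_swapped_mates_are_duplicates(self):
        a = mk_pair("chr1", 100, "+", "chr1", 500, "-", name="a")
        b = mk_pair("chr1", 500, "-", "chr1", 100, "+", name="b")
        kept, dupes = deduplicate([a, b])
        assert len(kept) == 1 and dupes == 1

    def test_one_bp_shift_not_duplicate(self):
        a = mk_pair("chr1", 100, "+", "chr1", 500, "-")
        b = mk_pair("chr1", 101, "+", "chr1", 500, "-")
        kept, dupes = deduplicate([a, b])
        assert len(kept) == 2 and dupes == 0

    def test_first_seen_retained(self):
        pairs = [mk_pair("chr1", 1, "+", "chr1", 9, "-", name=f"n{i}") for i in range(3)]
        kept, dupes = deduplicate(pairs)
        assert kept[0].name == "n0" and dupes == 2


class TestDangling:
    def test_forward_at_digest_start(self, dmap):
        p = mk_pair("chr1", 401, "+", "chr1", 700, "-")
        assert is_dangling(p, dmap)

    def test_reverse_at_digest_end(self, dmap):
        p = mk_pair("chr1", 500, "+", "chr1", 800, "-")
        assert is_dangling(p, dmap)

    def test_interior_ends_not_dangling(self, dmap):
        p = mk_pair("chr1", 500, "+", "chr1", 700, "-")
        assert not is_dangling(p, dmap)

    def test_forward_at_digest_end_not_dangling(self, dmap):
        # a forward read 5' at the digest END is interior to the ligation model
        p = mk_pair("chr1", 800, "+", "chr1", 700, "-")
        assert not is_dangling(p, dmap)


def _write_sam(path, dmap, records):
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": dmap.chromosome_length(c)} for c in dmap.chromosomes],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, chrom, pos0, rev, mapq, flags in records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            rec.query_sequence = "A" * 10
            if chrom is None:
                rec.is_unmapped = True
            else:
                rec.reference_name = chrom
                rec.reference_start = pos0
                rec.cigarstring = "10M"
                rec.mapping_quality = mapq
                rec.is_reverse = rev
                rec.is_secondary = "secondary" in flags
            out.write(rec)


class TestRePair:
    def test_three_pairs(self, dmap, tmp_path):
        recs1 = [(f"n{i}", "chr1", 100 * i + 10, False, 60, "") for i in range(3)]
        recs2 = [(f"n{i}", "chr1", 100 * i + 300, True, 60, "") for i in range(3)]
        s1, s2 = tmp_path / "1.sam", tmp_path / "2.sam"
        _write_sam(s1, dmap, recs1)
        _write_sam(s2, dmap, recs2)
        pairs, counters, _ = re_pair(s1, s2)
        assert len(pairs) == 3 and counters.total_pairs == 3
        # 5' coordinates: forward = pos0+1, reverse = pos0+readlen
        assert pairs[0].fwd.five_prime == 11
        assert pairs[0].rev.five_prime == 310

    def test_unmapped_mate_counted_not_emitted(self, dmap, tmp_path):
        s1, s2 = tmp_path / "1.sam", tmp_path / "2.sam"
        _write_sam(s1, dmap, [("n0", None, 0, False, 0, "")])
        _write_sam(s2, dmap, [("n0", "chr1", 50, False, 60, "")])
        pairs, counters, _ = re_pair(s1, s2)
        assert pairs == [] and counters.unmapped_pairs == 1

    def test_low_mapq_counts_as_multimapped(self, dmap, tmp_path):
        s1, s2 = tmp_path / "1.sam", tmp_path / "2.sam"
        _write_sam(s1, dmap, [("n0", "chr1", 10, False, 10, "")])
        _write_sam(s2, dmap, [("n0", "chr1", 50, False, 60, "")])
        pairs, counters, _ = re_pair(s1, s2, min_mapq=30)
        assert pairs == [] and counters.multimapped_pairs == 1

    def test_secondary_records_mean_multimapped(self, dmap, tmp_path):
        s1, s2 = tmp_path / "1.sam", tmp_path / "2.sam"
        _write_sam(s1, dmap, [
            ("n0", "chr1", 10, False, 0, ""),
            ("n0", "chr1", 900, False, 0, "secondary"),
        ])
        _write_sam(s2, dmap, [("n0", "chr1", 50, False, 60, "")])
        pairs, counters, _ = re_pair(s1, s2)
        assert pairs == [] and counters.multimapped_pairs == 1

    def test_name_in_one_stream_only_fatal(self, dmap, tmp_path):
        s1, s2 = tmp_path / "1.sam", tmp_path / "2.sam"
        _write_sam(s1, dmap, [("n0", "chr1", 10, False, 60, "")])
        _write_sam(s2, dmap, [("nX", "chr1", 50, False, 60, "")])
        with pytest.raises(ValueError, match="out of sync"):
            re_pair(s1, s2)


class TestClassifyPairs:
    def test_partition_and_conservation(self, dmap):
        rng = np.random.default_rng(4)
        chroms = dmap.chromosomes
        pairs = []
        for i in range(500):
            c1, c2 = rng.choice(chroms, size=2)
            pairs.append(mk_pair(
                c1, int(rng.integers(1, dmap.chromosome_length(c1) + 1)),
                str(rng.choice(["+", "-"])),
                c2, int(rng.integers(1, dmap.chromosome_length(c2) + 1)),
                str(rng.choice(["+", "-"])), name=f"p{i}",
            ))
        deduped, c = classify_pairs(pairs, dmap)
        assert c.remaining_pairs + c.duplicated == len(pairs)
        assert (
            c.unligated + c.self_ligated + c.strange_internal + c.chimeric
            == c.remaining_pairs
        )
        assert c.cis + c.trans == c.chimeric
        assert c.valid + c.chimeric_too_short + c.chimeric_too_long == c.chimeric
        assert all(p.category is not None for p in deduped)
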