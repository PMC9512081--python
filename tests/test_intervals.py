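import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_set
from _oracles import bitmap, coverage_counts, mask_to_intervals, random_intervals
from peakenrich.genome import GenomeSpec
from peakenrich.intervals import (GenomicInterval, IntervalSet, classify_peaks,
                                  consensus, distance, merge, overlap_bases,
                                  overlaps_any, read_bed, shuffle, subtract,
                                  tile_windows, write_bed)

LENGTHS = {"chr1": 10_000, "chr2": 10_000}


def spans(s: IntervalSet, chrom="chr1"):
    return list(zip(s.starts(chrom).tolist(), s.ends(chrom).tolist()))


# ---------------------------------------------------------------- BED I/O


def test_read_bed_single_record(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t100\n")
    s = read_bed(p)
    assert spans(s) == [(0, 100)]


def test_read_bed_rejects_empty_interval(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t100\n")
    with pytest.raises(ValueError, match="line 1"):
        read_bed(p)


def test_read_bed_sorts_unsorted_records(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr2\t5\t50\nchr1\t300\t400\nchr1\t0\t100\n")
    s = read_bed(p)
    assert len(s) == 3
    assert spans(s, "chr1") == [(0, 100), (300, 400)]
    assert spans(s, "chr2") == [(5, 50)]


def test_read_bed_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t100\nchr1\tzero\t100\n")
    with pytest.raises(ValueError, match="line 2"):
        read_bed(p)


def test_read_bed_unknown_chrom_errors(tmp_path, toy_genome):
    p = tmp_path / "a.bed"
    p.write_text("chrX\t0\t100\n")
    with pytest.raises(ValueError, match="chrX"):
        read_bed(p, genome=toy_genome)


def test_bed_round_trip_preserves_set(tmp_path):
    ivs = [GenomicInterval("chr1", 0, 100, name="p1", score=3.5, strand="+"),
           GenomicInterval("chr2", 5, 10, name="p2", score=1.0, strand="-")]
    s = IntervalSet(ivs)
    path = tmp_path / "out.bed"
    write_bed(s, path)
    assert len(path.read_text().splitlines()[0].split("\t")) == 6
    assert read_bed(path) == s


def test_write_bed_empty_set_and_bed3(tmp_path):
    write_bed(IntervalSet(), tmp_path / "empty.bed")
    assert (tmp_path / "empty.bed").read_text() == ""
    write_bed(make_set([(0, 5)]), tmp_path / "b3.bed")
    assert (tmp_path / "b3.bed").read_text() == "chr1\t0\t5\n"


# ---------------------------------------------------------------- merge


@pytest.mark.parametrize("inp, gap, expected", [
    ([(0, 100), (50, 150)], 0, [(0, 150)]),
    ([(0, 100), (100, 200)], 0, [(0, 200)]),  # book-ended join at gap 0
    ([(0, 100), (110, 200)], 0, [(0, 100), (110, 200)]),
    ([(0, 100), (110, 200)], 10, [(0, 200)]),
])
def test_merge_examples(inp, gap, expected):
    assert spans(merge(make_set(inp), gap=gap)) == expected


def test_merge_preserves_covered_bases(rng):
    s = IntervalSet(random_intervals(rng, LENGTHS, 50))
    m = merge(s)
    masks = bitmap(s, LENGTHS)
    assert m.covered_bases() == sum(int(v.sum()) for v in masks.values())
    assert m.covered_bases() == s.covered_bases()


# ---------------------------------------------------------------- subtract


@pytest.mark.parametrize("a, b, expected", [
    ([(0, 100)], [(40, 60)], [(0, 40), (60, 100)]),
    ([(0, 100)], [(0, 100)], []),
    ([(0, 100)], [(200, 300)], [(0, 100)]),
])
def test_subtract_examples(a, b, expected):
    assert spans(subtract(make_set(a), make_set(b))) == expected


def test_subtract_matches_bitmap_oracle(rng):
    s = IntervalSet(random_intervals(rng, LENGTHS, 40))
    e = IntervalSet(random_intervals(rng, LENGTHS, 40))
    result = subtract(s, e)
    sm, em = bitmap(s, LENGTHS), bitmap(e, LENGTHS)
    for chrom in LENGTHS:
        expected = mask_to_intervals(sm[chrom] & ~em[chrom])
        got = bitmap(result, LENGTHS)[chrom]
        assert mask_to_intervals(got) == expected


# ---------------------------------------------------------------- overlap


def test_overlaps_any_half_open_semantics():
    q = make_set([(0, 100)])
    assert overlaps_any(q, make_set([(99, 200)])).tolist() == [True]
    assert overlaps_any(q, make_set([(100, 200)])).tolist() == [False]


def test_overlaps_any_matches_bitmap_oracle(rng):
    q = IntervalSet(random_intervals(rng, LENGTHS, 60))
    s = IntervalSet(random_intervals(rng, LENGTHS, 60))
    masks = bitmap(s, LENGTHS)
    expected = [bool(masks[iv.chrom][iv.start:iv.end].any()) for iv in q]
    assert overlaps_any(q, s).tolist() == expected


def test_overlap_bases_matches_bitmap(rng):
    q = IntervalSet(random_intervals(rng, LENGTHS, 40))
    s = IntervalSet(random_intervals(rng, LENGTHS, 40))
    masks = bitmap(s, LENGTHS)
    expected = [int(masks[iv.chrom][iv.start:iv.end].sum()) for iv in q]
    assert overlap_bases(q, s).tolist() == expected


# ---------------------------------------------------------------- distance


def test_distance_gap_overlap_and_cross_chromosome():
    assert distance(GenomicInterval("chr1", 1000, 1200),
                    GenomicInterval("chr1", 1300, 2000)) == 100
    assert distance(GenomicInterval("chr1", 0, 100),
                    GenomicInterval("chr1", 50, 150)) == 0
    assert distance(GenomicInterval("chr1", 0, 100),
                    GenomicInterval("chr1", 100, 200)) == 0  # abutting
    assert distance(GenomicInterval("chr1", 0, 100),
                    GenomicInterval("chr2", 0, 100)) is None


# ---------------------------------------------------------------- windows


def test_tile_windows_counts_and_exclusion():
    g = GenomeSpec([("chr1", 1050)])
    assert len(tile_windows(g, 100)) == 10
    excluded = make_set([(150, 160)])
    w = tile_windows(g, 100, excluded=excluded)
    assert len(w) == 9
    assert (100, 200) not in spans(w)
    g2 = GenomeSpec([("chr1", 1000), ("chr2", 250)])
    assert len(tile_windows(g2, 100)) == 12


# ---------------------------------------------------------------- consensus


def test_consensus_three_sets_full_support():
    a, b, c = make_set([(0, 100)]), make_set([(50, 150)]), make_set([(80, 90)])
    assert spans(consensus([a, b, c], 3)) == [(80, 90)]
    assert spans(consensus([a, b, c], 2)) == [(50, 100)]


def test_consensus_single_set_is_merge():
    s = make_set([(0, 100), (50, 120), (300, 400)])
    assert consensus([s], 1) == merge(s)


def test_consensus_matches_coverage_oracle_and_is_antitone(rng):
    sets = [IntervalSet(random_intervals(rng, LENGTHS, 30)) for _ in range(3)]
    counts = coverage_counts(sets, LENGTHS)
    prev = None
    for k in (1, 2, 3):
        got = consensus(sets, k)
        for chrom in LENGTHS:
            assert mask_to_intervals(counts[chrom] >= k) == spans(got, chrom)
        if prev is not None:
            assert got.covered_bases() <= prev
        prev = got.covered_bases()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 120)),
                min_size=1, max_size=25),
       st.lists(st.tuples(st.integers(0, 900), st.integers(1, 120)),
                min_size=1, max_size=25))
def test_merge_of_union_equals_min_support_one(a_sp, b_sp):
    lengths = {"chr1": 1024}
    a = make_set([(s, s + l) for s, l in a_sp])
    b = make_set([(s, s + l) for s, l in b_sp])
    union = IntervalSet(list(a) + list(b))
    assert consensus([a, b], 1) == merge(union)
    counts = coverage_counts([a, b], lengths)
    assert mask_to_intervals(counts["chr1"] >= 2) == spans(consensus([a, b], 2))


# ---------------------------------------------------------------- shuffle


def test_shuffle_preserves_counts_lengths_and_is_deterministic(toy_genome, rng):
    s = IntervalSet(random_intervals(rng, LENGTHS, 50))
    a = shuffle(s, toy_genome, seed=11)
    b = shuffle(s, toy_genome, seed=11)
    assert a == b
    for chrom in LENGTHS:
        assert len(a.starts(chrom)) == len(s.starts(chrom))
        assert sorted((a.ends(chrom) - a.starts(chrom)).tolist()) == \
            sorted((s.ends(chrom) - s.starts(chrom)).tolist())
    assert shuffle(s, toy_genome, seed=12) != a


def test_shuffle_avoids_excluded_regions(toy_genome, rng):
    s = IntervalSet(random_intervals(rng, LENGTHS, 30, max_len=50))
    excluded = make_set([(0, 4000)])  # 40% of chr1
    sh = shuffle(s, toy_genome, excluded=excluded, seed=5)
    assert not overlaps_any(sh, excluded).any()


def test_shuffle_start_is_uniform():
    """10,000 shuffles of a 100 bp interval on a 1,000 bp chromosome: the
    start should be discrete-uniform on [0, 900]; chi-square GOF at a=0.001."""
    g = GenomeSpec([("chr1", 1000)])
    s = make_set([(0, 100)])
    rng = np.random.default_rng(99)
    starts = [int(shuffle(s, g, seed=rng).starts("chr1")[0]) for _ in range(10_000)]
    counts, _ = np.histogram(starts, bins=10, range=(0, 901))
    p = stats.chisquare(counts).pvalue
    assert p > 0.001


def test_shuffle_impossible_interval_errors():
    with pytest.raises(ValueError, match="longer than chromosome"):
        shuffle(make_set([(0, 50)]), GenomeSpec([("chr1", 40)]), seed=0)


# ---------------------------------------------------------------- classify


def test_classify_peaks_fractions():
    peaks = make_set([(i * 100, i * 100 + 50) for i in range(10)])
    marks = make_set([(20, 40)])  # overlaps peak 0 only
    labels = classify_peaks(peaks, marks)
    assert labels.fraction_euchromatic == pytest.approx(0.9)
    assert labels.fraction_heterochromatic == pytest.approx(0.1)
    assert len(labels.euchromatic) == 9 and len(labels.heterochromatic) == 1
    assert labels.fraction_euchromatic + labels.fraction_heterochromatic == 1.0


def test_classify_peaks_empty_marks_all_euchromatic(rng):
    peaks = IntervalSet(random_intervals(rng, LENGTHS, 10))
    labels = classify_peaks(peaks, IntervalSet())
    assert labels.fraction_euchromatic == 1.0
    assert len(labels.heterochromatic) == 0


def test_classify_peaks_agrees_with_bitmap_oracle(rng):
    peaks = IntervalSet(random_intervals(rng, LENGTHS, 40))
    marks = IntervalSet(random_intervals(rng, LENGTHS, 20))
    evidence = IntervalSet(random_intervals(rng, LENGTHS, 20), label="atac")
    labels = classify_peaks(peaks, marks, [evidence])
    masks = bitmap(marks, LENGTHS)
    expected = ["heterochromatic" if masks[iv.chrom][iv.start:iv.end].any()
                else "euchromatic" for iv in peaks]
    assert labels.labels == expected
    ev_masks = bitmap(evidence, LENGTHS)
    frac = np.mean([bool(ev_masks[iv.chrom][iv.start:iv.end].any())
                    for iv in peaks])
    assert labels.evidence_fractions["atac"] == pytest.approx(frac)
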