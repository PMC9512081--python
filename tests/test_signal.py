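import math

import numpy as np
import pytest

from conftest import make_set
from peakenrich.annotation import GeneModel, GeneTable
from peakenrich.genome import GenomeSpec
from peakenrich.signal import (SignalTrack, bin_log2_ratio,
                               gene_body_ratio_comparison, mean_over_intervals,
                               read_bedgraph, two_sample_ttest, write_bedgraph)


@pytest.fixture
def genome():
    return GenomeSpec([("chr1", 1000)])


def constant_track(genome, value):
    return SignalTrack(genome, {c: (np.array([0]), np.array([l]),
                                    np.array([float(value)]))
                                for c, l in genome})


# ---------------------------------------------------------------- bedGraph


def test_read_bedgraph_basic(tmp_path, genome):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t100\t2.0\n")
    t = read_bedgraph(p, genome)
    assert t.integral("chr1", np.array([100]))[0] == pytest.approx(200.0)
    assert t.integral("chr1", np.array([1000]))[0] == pytest.approx(200.0)


def test_read_bedgraph_overlap_errors(tmp_path, genome):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t100\t2.0\nchr1\t50\t150\t1.0\n")
    with pytest.raises(ValueError, match="overlap"):
        read_bedgraph(p, genome)


def test_read_bedgraph_negative_value_errors(tmp_path, genome):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t100\t-1.0\n")
    with pytest.raises(ValueError):
        read_bedgraph(p, genome)


def test_bedgraph_round_trip(tmp_path, genome, rng):
    vals = rng.integers(0, 5, size=20).astype(float)
    t = SignalTrack.from_bins(genome, 50, {"chr1": vals})
    path = tmp_path / "t.bedgraph"
    write_bedgraph(t, path)
    back = read_bedgraph(path, genome)
    edges = np.arange(0, 1001, 50)
    assert np.allclose(np.diff(back.integral("chr1", edges)),
                       np.diff(t.integral("chr1", edges)))


# ---------------------------------------------------------------- log ratio


def test_constant_tracks_give_exact_log2(genome):
    a, b = constant_track(genome, 4.0), constant_track(genome, 2.0)
    ratio = bin_log2_ratio(a, b, bin=50, pseudocount=0.0)
    assert np.allclose(ratio.values["chr1"], 1.0)


def test_identical_tracks_give_zero_everywhere(genome, rng):
    vals = rng.poisson(5, size=20).astype(float)
    a = SignalTrack.from_bins(genome, 50, {"chr1": vals})
    ratio = bin_log2_ratio(a, a, bin=50, pseudocount=1.0)
    assert np.allclose(ratio.values["chr1"], 0.0)


def test_swapping_tracks_negates_bins(genome, rng):
    a = SignalTrack.from_bins(genome, 50, {"chr1": rng.poisson(5, 20).astype(float)})
    b = SignalTrack.from_bins(genome, 50, {"chr1": rng.poisson(9, 20).astype(float)})
    ab = bin_log2_ratio(a, b, bin=50)
    ba = bin_log2_ratio(b, a, bin=50)
    assert np.allclose(ab.values["chr1"], -ba.values["chr1"])


def test_zero_pseudocount_with_zero_bin_errors(genome):
    a = constant_track(genome, 1.0)
    z = SignalTrack(genome, {"chr1": (np.array([0]), np.array([100]),
                                      np.array([1.0]))})
    with pytest.raises(ValueError, match="pseudocount 0"):
        bin_log2_ratio(a, z, bin=50, pseudocount=0.0)


def test_bin_means_match_per_base_oracle(genome, rng):
    # irregular piecewise track vs brute-force per-base averaging
    cuts = np.sort(rng.choice(np.arange(1, 1000), size=12, replace=False))
    bounds = np.concatenate([[0], cuts, [1000]])
    vals = rng.uniform(0, 10, size=len(bounds) - 1)
    a = SignalTrack(genome, {"chr1": (bounds[:-1], bounds[1:], vals)})
    b = constant_track(genome, 3.0)
    ratio = bin_log2_ratio(a, b, bin=50, pseudocount=1.0)
    per_base = np.repeat(vals, np.diff(bounds))
    expected = np.log2((per_base.reshape(20, 50).mean(axis=1) + 1.0) / 4.0)
    assert np.allclose(ratio.values["chr1"], expected, atol=1e-12)


# ---------------------------------------------------------------- aggregation


def test_mean_over_intervals_examples(genome):
    vals = np.zeros(20)
    vals[0] = vals[1] = 1.0  # bins [0,50) and [50,100)
    ratio = bin_log2_ratio(
        SignalTrack.from_bins(genome, 50, {"chr1": 3.0 * (2.0 ** vals) - 1.0}),
        constant_track(genome, 2.0), bin=50, pseudocount=1.0)
    assert np.allclose(ratio.values["chr1"][:3], [1, 1, 0])
    # region spanning bins valued {1, 1, 0} -> 2/3
    m = mean_over_intervals(ratio, make_set([(0, 150)]))
    assert m[0] == pytest.approx(2 / 3)
    # short region containing exactly one midpoint -> that bin's value
    m = mean_over_intervals(ratio, make_set([(20, 30)]))
    assert m[0] == pytest.approx(1.0)
    # region containing no midpoint -> nan sentinel
    m = mean_over_intervals(ratio, make_set([(30, 40)]))
    assert math.isnan(m[0])


def test_mean_over_intervals_matches_direct_recomputation(genome, rng):
    vals = rng.normal(size=20)
    ratio = bin_log2_ratio(
        SignalTrack.from_bins(genome, 50, {"chr1": 5 * 2.0 ** vals}),
        constant_track(genome, 5.0), bin=50, pseudocount=0.0)
    regions = make_set([(0, 1000), (120, 480), (75, 125)])
    got = mean_over_intervals(ratio, regions)
    mids = np.arange(20) * 50 + 25
    for (s, e), m in zip([(0, 1000), (75, 125), (120, 480)], got):
        keep = (mids >= s) & (mids < e)
        assert m == pytest.approx(ratio.values["chr1"][keep].mean())


# ---------------------------------------------------------------- t test


def test_pooled_t_example():
    t, p = two_sample_ttest([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-1.2247, abs=1e-4)
    assert p == pytest.approx(0.2878, abs=1e-4)


def test_identical_groups_and_scale_invariance(rng):
    x = rng.normal(size=10)
    t, p = two_sample_ttest(x, x)
    assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
    y = rng.normal(1, 2, size=8)
    t1, p1 = two_sample_ttest(x, y)
    t2, p2 = two_sample_ttest(3.5 * x, 3.5 * y)
    assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)


def test_zero_variance_edge_cases():
    assert two_sample_ttest([2, 2, 2], [2, 2]) == (0.0, 1.0)
    with pytest.warns(UserWarning):
        t, p = two_sample_ttest([2, 2, 2], [3, 3])
    assert p == 0.0 and t == -math.inf


def test_student_equals_welch_for_balanced_equal_variance():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [2.5, 3.5, 4.5, 5.5]  # same spread, same n
    ts, ps = two_sample_ttest(x, y, "student")
    tw, pw = two_sample_ttest(x, y, "welch")
    assert ts == pytest.approx(tw, abs=1e-9) and ps == pytest.approx(pw, abs=1e-9)


def test_ttest_input_validation():
    with pytest.raises(ValueError):
        two_sample_ttest([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        two_sample_ttest([1.0, np.nan], [1.0, 2.0])


# ---------------------------------------------------------------- composition


def test_halved_signal_over_down_genes_recovers_minus_one():
    genome = GenomeSpec([("chr1", 200_000)])
    genes = GeneTable([GeneModel(f"g{i}", "chr1", i * 10_000 + 1000,
                                 i * 10_000 + 9000, "+") for i in range(20)])
    classes = {f"g{i}": ("down" if i < 6 else "unchanged") for i in range(20)}
    rng = np.random.default_rng(13)
    n_bins = 200_000 // 50
    mids = np.arange(n_bins) * 50 + 25
    down = np.zeros(n_bins, dtype=bool)
    for i in range(6):
        down |= (mids >= i * 10_000 + 1000) & (mids < i * 10_000 + 9000)
    wt = SignalTrack.from_bins(genome, 50,
                               {"chr1": rng.poisson(50, n_bins).astype(float)})
    ko = SignalTrack.from_bins(genome, 50, {"chr1": rng.poisson(
        np.where(down, 25.0, 50.0)).astype(float)})
    comp = gene_body_ratio_comparison(ko, wt, genes, classes, bin=50)
    down_means = comp.class_values("down")
    assert len(down_means) == 6
    assert abs(float(down_means.mean()) - (-1.0)) < 0.15
    t, df, p = comp.tests["down_vs_unchanged"]
    assert p < 1e-6 and t < 0
    assert df == 6 + 14 - 2


def test_label_permutation_destroys_planted_effect():
    genome = GenomeSpec([("chr1", 100_000)])
    genes = GeneTable([GeneModel(f"g{i}", "chr1", i * 10_000 + 1000,
                                 i * 10_000 + 9000, "+") for i in range(10)])
    rng = np.random.default_rng(5)
    n_bins = 100_000 // 50
    mids = np.arange(n_bins) * 50 + 25
    down = np.zeros(n_bins, dtype=bool)
    for i in range(3):
        down |= (mids >= i * 10_000 + 1000) & (mids < i * 10_000 + 9000)
    wt = SignalTrack.from_bins(genome, 50,
                               {"chr1": rng.poisson(50, n_bins).astype(float)})
    ko = SignalTrack.from_bins(genome, 50, {"chr1": rng.poisson(
        np.where(down, 25.0, 50.0)).astype(float)})
    true_classes = {f"g{i}": ("down" if i < 3 else "unchanged") for i in range(10)}
    comp = gene_body_ratio_comparison(ko, wt, genes, true_classes, bin=50)
    assert comp.tests["down_vs_unchanged"][2] < 1e-6
    ids = list(true_classes)
    big_p = 0
    n_perm = 40
    for _ in range(n_perm):
        perm = rng.permutation(ids)
        permuted = {g: true_classes[ids[i]] for i, g in enumerate(perm)}
        c = gene_body_ratio_comparison(ko, wt, genes, permuted, bin=50)
        if c.tests["down_vs_unchanged"][2] > 0.01:
            big_p += 1
    assert big_p >= 0.8 * n_perm
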