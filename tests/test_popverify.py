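"""Depth normalization, regional means, flank design, rank-sum testing and
overlap ratios."""

import itertools

import numpy as np
import pytest

from triosv.models import BedRecord, CoverageTrack
from triosv.popverify import (
    PopVerifyError,
    flank_design,
    normalize_depth,
    overlap_ratio,
    ranksum_test,
    regional_mean,
    species_profile,
    verify_insertion,
)
from triosv.synthetic_trio import simulate_population_coverage


def _track(depth, sample="s", species="x", start=0, seq_depth=1.0):
    depth = np.asarray(depth, float)
    return CoverageTrack(sample, species, "c1", start, start + len(depth), depth,
                         seq_depth)


# --- normalization & profiles ------------------------------------------------


def test_normalize_divides_by_sample_depth():
    t = _track([60.0] * 10, seq_depth=30.0)
    assert np.allclose(normalize_depth(t), 2.0)


def test_normalize_zero_depth_rejected():
    with pytest.raises(PopVerifyError, match="positive"):
        normalize_depth(_track([1.0], seq_depth=0.0))


def test_normalize_is_linear():
    d = np.arange(10.0)
    a = normalize_depth(_track(d, seq_depth=5.0))
    b = normalize_depth(_track(2 * d, seq_depth=5.0))
    assert np.allclose(b, 2 * a)


def test_profile_single_sample_equals_normalized_track():
    t = _track([4.0, 8.0], seq_depth=4.0)
    assert np.allclose(species_profile([t]), [1.0, 2.0])


def test_profile_averages_base_by_base():
    a = _track([1.0, 1.0])
    b = _track([3.0, 5.0])
    assert np.allclose(species_profile([a, b]), [2.0, 3.0])


def test_profile_region_mismatch_rejected():
    with pytest.raises(PopVerifyError, match="covers"):
        species_profile([_track([1.0] * 5), _track([1.0] * 6)])


def test_noncarrier_profile_dips_to_zero_inside_insertion():
    tracks = simulate_population_coverage(("c", 0, 3000), (1000, 2000), 11, 12,
                                          noise_fraction=0.0, seed=1)
    wolves = [t for t in tracks if t.species == "wolf"]
    prof = species_profile(wolves)
    assert prof[1000:2000].max() == 0.0
    assert abs(prof[:1000].mean() - 1.0) < 0.1


# --- regional means ----------------------------------------------------------


def test_regional_mean_constant():
    assert regional_mean(_track([2.0] * 10), (2, 8)) == 2.0


def test_regional_mean_half_and_half():
    assert regional_mean(_track([0.0] * 5 + [2.0] * 5), (0, 10)) == 1.0


def test_regional_mean_matches_per_base_loop():
    rng = np.random.default_rng(0)
    d = rng.poisson(7, 500).astype(float)
    t = _track(d, start=100, seq_depth=3.0)
    got = regional_mean(t, (150, 430))
    exp = sum(d[i - 100] / 3.0 for i in range(150, 430)) / (430 - 150)
    assert got == pytest.approx(exp)


def test_regional_mean_empty_interval_rejected():
    with pytest.raises(PopVerifyError, match="empty"):
        regional_mean(_track([1.0] * 10), (5, 5))


# --- flank design ------------------------------------------------------------


def test_flank_design_basic():
    left, inner, right = flank_design(("c", 1000, 1500))
    assert left == (500, 1000) and inner == (1000, 1500) and right == (1500, 2000)


def test_flank_design_matches_reported_verification_window():
    """The canonical AKR1B1 case: insertion chr14:31644131-31645486 (1-based)
    analysed in a window of three insertion lengths (31642776-31646841)."""
    left, inner, right = flank_design(("chr14", 31644130, 31645486))
    window = (left[0], right[1])
    assert right[1] - left[0] == 3 * (31645486 - 31644130)
    # printed window bounds agree with the flank construction to within 2 bp
    assert abs(window[0] - (31642776 - 1)) <= 2
    assert abs(window[1] - 31646841) <= 2


def test_flank_design_out_of_bounds():
    with pytest.raises(PopVerifyError, match="flank"):
        flank_design(("c", 100, 400))
    with pytest.raises(PopVerifyError, match="flank"):
        flank_design(("c", 600, 900), chrom_length=1000)


# --- rank-sum test -----------------------------------------------------------


def exact_two_sided_p(x, y):
    """Enumeration oracle over all rank assignments."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), 1)}
    obs = sum(ranks[v] for v in x)
    stats = []
    for combo in itertools.combinations(range(1, n + 1), nx):
        stats.append(sum(combo))
    stats = np.array(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-9)
    return float(p)


def test_ranksum_small_example_exact():
    res = ranksum_test([1, 2], [3, 4])
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(1 / 3)


def test_ranksum_identical_groups_p_one():
    res = ranksum_test([1, 2, 3], [1, 2, 3])
    assert res.pvalue == pytest.approx(1.0)


def test_ranksum_degenerate_constant_data():
    res = ranksum_test([5, 5], [5, 5, 5])
    assert res.degenerate and res.pvalue == 1.0


@pytest.mark.parametrize("seed", range(12))
def test_ranksum_exact_branch_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    nx = int(rng.integers(2, 5))
    ny = int(rng.integers(2, 11 - nx))
    pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
    x, y = pooled[:nx], pooled[nx:]
    res = ranksum_test(x, y)
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)


def test_ranksum_switches_to_asymptotic_for_large_or_tied_samples():
    assert ranksum_test(np.arange(8.0), np.arange(8.0) + 0.5).method == "asymptotic"
    assert ranksum_test([1.0, 2.0, 2.0], [3.0, 4.0]).method == "asymptotic"


def test_verify_insertion_separates_groups():
    tracks = simulate_population_coverage(("c", 0, 3000), (1000, 2000), 11, 12,
                                          noise_fraction=0.01, seed=3)
    report = verify_insertion(tracks, ("c", 1000, 2000))
    assert report.interior_means["dog"] > 0.8
    assert report.interior_means["wolf"] < 0.1
    assert abs(report.flank_means["dog"] - report.flank_means["wolf"]) < 0.05
    assert report.ranksum.pvalue < 0.01


# --- overlap ratio -----------------------------------------------------------


def test_overlap_ratio_examples():
    a = [BedRecord("c1", 0, 100)]
    assert overlap_ratio(a, [BedRecord("c1", 50, 150)]) == 1.0
    assert overlap_ratio(a, [BedRecord("c1", 200, 300)]) == 0.0
    assert overlap_ratio(a, [BedRecord("c2", 0, 100)]) == 0.0


def test_overlap_ratio_empty_denominator_rejected():
    with pytest.raises(PopVerifyError, match="undefined"):
        overlap_ratio([], [BedRecord("c1", 0, 10)])


def test_overlap_ratio_matches_quadratic_brute_force():
    rng = np.random.default_rng(7)

    def random_set(n):
        out = []
        for _ in range(n):
            s = int(rng.integers(0, 50_000))
            out.append(BedRecord(f"c{rng.integers(1, 4)}", s, s + int(rng.integers(1, 400))))
        return out

    a, b = random_set(500), random_set(300)
    brute = sum(
        1
        for r in a
        if any(r.chrom == s.chrom and r.start < s.end and s.start < r.end for s in b)
    ) / len(a)
    assert overlap_ratio(a, b) == pytest.approx(brute)
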