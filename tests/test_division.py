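"""Prey-division summaries and tests: shares, uniformity, efficiency, rate."""

import numpy as np
import pytest
from scipy import stats

from helpers import hunt_from_ids
from huntdiv.division import (
    IndividualTally,
    capture_efficiency_test,
    capture_rate_series,
    rank_correlation,
    share_curve,
    tally,
    top_share,
    uniformity_test,
)
from huntdiv.simulate import HuntConfig, generate_hunt, true_group_assignment
from huntdiv.subgroups import GroupAssignment


def _tally(seqs, caps, dashes=None):
    return [
        IndividualTally(
            individual_id=f"m{j}",
            subgroup=0,
            n_sequences=s,
            n_dashes=d if dashes is None else dashes[j],
            n_captures=c,
        )
        for j, (s, c, d) in enumerate(zip(seqs, caps, [3 * s for s in seqs]))
    ]


def test_tally_hand_count(make_hunt):
    hunt = make_hunt(list("AABBA"), captures=[1, 0, 0, 1, 0])
    ga = GroupAssignment(threshold=float("nan"), groups=(("A", "B"),), epoch_starts=(0,))
    rows = {t.individual_id: t for t in tally(hunt, ga)}
    assert (rows["A"].n_sequences, rows["A"].n_dashes, rows["A"].n_captures) == (2, 3, 1)
    assert (rows["B"].n_sequences, rows["B"].n_dashes, rows["B"].n_captures) == (1, 2, 1)
    assert sum(t.n_captures for t in rows.values()) == int(hunt.capture.sum())
    assert rows["A"].capture_efficiency == pytest.approx(1 / 3)


def test_tally_zero_capture_efficiency(make_hunt):
    hunt = make_hunt(list("AB"))
    ga = GroupAssignment(threshold=float("nan"), groups=(("A", "B"),), epoch_starts=(0,))
    assert all(t.capture_efficiency == 0.0 for t in tally(hunt, ga))


def test_top_share_worked_example():
    # sequences [10,5,3,2], captures [5,3,1,1]: top 2 of 4 hold 80%
    tl = _tally([10, 5, 3, 2], [5, 3, 1, 1])
    assert top_share(tl, 0.5) == pytest.approx(80.0)


def test_top_share_extremes():
    assert top_share(_tally([4, 3, 2, 1], [9, 0, 0, 0]), 0.5) == pytest.approx(100.0)
    with pytest.raises(ValueError, match="zero captures"):
        top_share(_tally([4, 3], [0, 0]), 0.5)


def test_top_share_odd_group_uses_ceiling():
    # ceil(0.5 * 3) = 2 individuals
    tl = _tally([5, 4, 3], [2, 1, 1])
    assert top_share(tl, 0.5) == pytest.approx(75.0)


def test_share_curve_shape_and_diagonal():
    tl = _tally([4, 3, 2, 1], [2, 2, 2, 2])
    curve = share_curve(tl)
    assert curve.pct_individuals[0] == 0.0 and curve.pct_individuals[-1] == 100.0
    assert curve.pct_captures[0] == 0.0 and curve.pct_captures[-1] == 100.0
    # equal captures: the curve is the diagonal
    assert curve.pct_captures == pytest.approx(curve.pct_individuals)
    # non-decreasing and concave for descending-sorted input
    skewed = share_curve(_tally([10, 5, 3, 2], [5, 3, 1, 1]))
    diffs = np.diff(skewed.pct_captures)
    assert np.all(diffs >= -1e-9)
    assert np.all(np.diff(diffs) <= 1e-9)


def test_uniformity_examples():
    res = uniformity_test([5, 5, 5, 5])
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 3
    res = uniformity_test([10, 2])
    assert res.chi2 == pytest.approx((10 - 6) ** 2 / 6 + (2 - 6) ** 2 / 6)
    assert uniformity_test([3, 2]).low_expected
    assert not uniformity_test([10, 12]).low_expected
    with pytest.raises(ValueError):
        uniformity_test([0, 0])


def test_rank_correlation_examples():
    assert rank_correlation([1, 2, 3, 4], [2, 4, 6, 9]).rho == pytest.approx(1.0)
    assert rank_correlation([1, 2, 3, 4], [9, 6, 4, 2]).rho == pytest.approx(-1.0)
    flagged = rank_correlation([1, 2, 3], [5, 5, 5])
    assert not flagged.defined


def test_rank_correlation_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(4, 15))
        x = rng.integers(0, 6, size=n).astype(float)
        y = x + rng.normal(0, 2, size=n)
        if np.all(x == x[0]):
            continue
        res = rank_correlation(x, y)
        rho_oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(rho_oracle)


def test_efficiency_test_identical_rows_not_significant():
    tl = _tally([10, 10], [5, 5])
    res = capture_efficiency_test(tl, replicates=2000, seed=0)
    assert res.p_value > 0.5


def test_efficiency_test_matches_exact_hypergeometric_2x2():
    rng = np.random.default_rng(7)
    for _ in range(25):
        d = rng.integers(5, 40, size=2)
        c = np.array([rng.integers(0, di + 1) for di in d])
        if c.sum() in (0, d.sum()):
            continue
        tl = [
            IndividualTally(f"m{j}", 0, 1, int(d[j]), int(c[j])) for j in range(2)
        ]
        mc = capture_efficiency_test(tl, replicates=4000, seed=int(rng.integers(2**31)))
        exact = stats.fisher_exact([[c[0], d[0] - c[0]], [c[1], d[1] - c[1]]])[1]
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(mc.p_value - exact) <= 5 * se + 2 / 4000


def test_efficiency_test_degenerate_margins():
    res = capture_efficiency_test(_tally([5, 5], [0, 0]), replicates=100, seed=0)
    assert res.p_value == 1.0 and res.degenerate
    with pytest.raises(ValueError):
        capture_efficiency_test(_tally([5], [1]), replicates=100, seed=0)


def test_efficiency_test_calibrated_under_equal_efficiency():
    rejections = 0
    n_hunts = 60
    for seed in range(n_hunts):
        hunt, truth = generate_hunt(
            HuntConfig(group_sizes=(6,), arrival_times_s=(0.0,), capture_p=0.2,
                       duration_s=1500.0, seed=3000 + seed)
        )
        ga = true_group_assignment(hunt, truth)
        res = capture_efficiency_test(tally(hunt, ga), replicates=499, seed=seed)
        rejections += res.p_value <= 0.05
    assert rejections / n_hunts <= 0.12  # ~alpha, generous margin at n=60


def test_capture_rate_constant_counts(make_hunt):
    # one capture exactly every 30 s: 2 per bin, zero slope
    times = np.arange(15.0, 600.0, 30.0)
    hunt = hunt_from_ids(
        ["A", "B"] * (len(times) // 2), captures=[True] * len(times), times=times,
        duration=600.0,
    )
    res = capture_rate_series(hunt)
    assert res.counts == tuple([2] * 10)
    assert res.slope == pytest.approx(0.0)
    assert res.f_stat == pytest.approx(0.0)
    assert res.se_per_bin == pytest.approx(0.0)


def test_capture_rate_perfect_line(make_hunt):
    # bins hold 0,1,2,3,4 captures: unit slope, F df (1, 3)
    times, caps = [], []
    for b in range(5):
        for j in range(b):
            times.append(60.0 * b + 5.0 * (j + 1))
            caps.append(True)
    times.append(299.0)
    caps.append(False)
    order = np.argsort(times)
    ids = ["A", "B"] * (len(times) // 2) + ["A"] * (len(times) % 2)
    hunt = hunt_from_ids(
        [ids[i] for i in order],
        captures=[caps[i] for i in order],
        times=sorted(times),
        duration=300.0,
    )
    res = capture_rate_series(hunt)
    assert res.counts == (0, 1, 2, 3, 4)
    assert res.slope == pytest.approx(1.0)
    assert res.df == (1, 3)
    assert res.p_value < 1e-6


def test_capture_rate_needs_two_bins(make_hunt):
    with pytest.raises(ValueError):
        capture_rate_series(hunt_from_ids(["A", "B"], times=[1.0, 2.0], duration=30.0))
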