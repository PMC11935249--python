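import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from letimpt import (DVH, IndexTable, LETdMap, VoxelGrid, delta_report,
                     dose_index, geud, index_table, let_indices, render_dose,
                     wilcoxon_signed_rank_exact)
from tests.conftest import toy_influence


# ---------------------------------------------------------------------------
# DVH indices


def brute_force_dv(doses, v):
    """Exhaustive threshold scan for Dv over the realized dose values."""
    doses = np.asarray(doses, float)
    best = 0.0
    for d in np.sort(doses):
        if np.mean(doses >= d) >= v:
            best = max(best, d)
    return best


def test_uniform_field_indices():
    d = np.full(50, 42.0)
    for idx in ("D98", "D2", "Dmean"):
        assert dose_index(d, 0.1, idx) == pytest.approx(42.0)


def test_quantiles_match_threshold_scan_oracle():
    d = np.arange(101, dtype=float)  # 0..100, equal-volume voxels
    assert dose_index(d, 0.1, "D98") == brute_force_dv(d, 0.98)
    assert dose_index(d, 0.1, "D2") == brute_force_dv(d, 0.02)
    rng = np.random.default_rng(4)
    rand = rng.uniform(0, 80, 57)
    for v in (0.98, 0.5, 0.02):
        assert dose_index(rand, 0.1, f"D{int(v*100)}") == pytest.approx(
            brute_force_dv(rand, v))


def test_d1cc_matches_cumulative_volume_walk():
    vv = 0.0625  # 16 voxels per cc
    d = np.sort(np.random.default_rng(1).uniform(10, 80, 200))[::-1]
    # direct cumulative-volume walk oracle, interpolating at exactly 1 cc
    k = 1.0 / vv
    k0 = int(np.floor(k))
    frac = k - k0
    expect = d[k0 - 1] * (1 - frac) + d[k0] * frac
    assert dose_index(d, vv, "D1cc") == pytest.approx(expect)
    with pytest.raises(ValueError, match="below 1 cc"):
        dose_index(d[:10], vv, "D1cc")


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.floats(0.0, 100.0), min_size=3, max_size=40),
       st.floats(0.05, 0.5), st.floats(0.5, 0.95))
def test_dv_monotone_in_volume(doses, v1, dv):
    v2 = min(v1 + dv, 1.0)
    d1 = dose_index(doses, 0.1, "D" + str(v1 * 100))
    d2 = dose_index(doses, 0.1, "D" + str(v2 * 100))
    assert d2 <= d1


def test_dvh_curve_and_volume_fraction():
    d = np.array([10.0, 20.0, 30.0, 40.0])
    dvh = DVH.from_doses("ctv", d, 0.5)
    assert dvh.volume_fraction_at(25.0) == 0.5
    curve = dvh.curve(bin_gy=10.0)
    assert curve.volume_fraction.iloc[0] == 1.0
    assert curve.volume_fraction.is_monotonic_decreasing


# ---------------------------------------------------------------------------
# gEUD


def test_geud_identities():
    u = np.full(20, 63.0)
    for a in (-10.0, 2.0, 11.11):
        assert geud(u, a) == pytest.approx(63.0)
    d = np.array([10.0, 30.0, 50.0])
    assert geud(d, 1.0) == pytest.approx(d.mean())
    # direct arithmetic for {78, 70}, a = -10
    expect = ((78.0**-10 + 70.0**-10) / 2.0) ** (-0.1)
    assert geud(np.array([78.0, 70.0]), -10.0) == pytest.approx(expect)


def test_geud_limits_approach_extrema():
    # plan-like doses (tight spread around prescription)
    d = np.random.default_rng(2).uniform(78, 80, 100)
    assert geud(d, 50.0) == pytest.approx(d.max(), rel=0.02)
    assert geud(d, -50.0) == pytest.approx(d.min(), rel=0.02)
    # and the approach is monotone in |a|
    assert abs(geud(d, 200.0) - d.max()) < abs(geud(d, 50.0) - d.max())
    assert abs(geud(d, -200.0) - d.min()) < abs(geud(d, -50.0) - d.min())


def test_geud_floor_and_errors():
    assert geud(np.array([0.0, 50.0]), -10.0) == pytest.approx(
        ((0.01**-10 + 50.0**-10) / 2) ** (-0.1))
    with pytest.raises(ValueError):
        geud(np.array([1.0]), 0.0)
    with pytest.raises(ValueError):
        geud(np.array([]), 2.0)


# ---------------------------------------------------------------------------
# LET indices


def _letd_map(values, zero=None):
    grid = VoxelGrid((len(values), 1, 1), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
    z = np.zeros(len(values), bool) if zero is None else np.asarray(zero)
    return LETdMap(grid, np.asarray(values, float), z), grid


def test_let_indices_uniform_and_quantile_bound():
    lmap, grid = _letd_map(np.full(60, 3.1))
    mask = np.ones(grid.dims, bool)
    mean_l, l98 = let_indices(lmap, mask)
    assert mean_l == pytest.approx(3.1) and l98 == pytest.approx(3.1)
    rng = np.random.default_rng(9)
    vals = rng.uniform(1, 7, 50)
    lmap, grid = _letd_map(vals)
    mean_l, l98 = let_indices(lmap, np.ones(grid.dims, bool))
    assert l98 <= vals.max()
    assert l98 == pytest.approx(brute_force_dv(vals, 0.98))


def test_let_indices_zero_dose_handling():
    vals = np.full(100, 2.0)
    zero = np.zeros(100, bool)
    zero[:3] = True  # 3% flagged: excluded but tolerated
    lmap, grid = _letd_map(vals, zero)
    mean_l, _ = let_indices(lmap, np.ones(grid.dims, bool))
    assert mean_l == pytest.approx(2.0)
    zero[:10] = True  # 10% flagged: plan invalid
    lmap, grid = _letd_map(vals, zero)
    with pytest.raises(ValueError, match="zero dose"):
        let_indices(lmap, np.ones(grid.dims, bool))


# ---------------------------------------------------------------------------
# rendering and delta reports


def test_render_linearity_and_partition_additivity(nominal):
    inf, grid = toy_influence(n_vox=12, n_spots=6, seed=5, with_let=False)
    w = np.random.default_rng(0).uniform(0, 2, 6)
    zero = render_dose(np.zeros(6), inf)
    assert np.all(zero.values == 0)
    full = render_dose(w, inf)
    double = render_dose(2 * w, inf)
    assert np.allclose(double.values, 2 * full.values)
    # additivity over a spot partition
    w1, w2 = w.copy(), w.copy()
    w1[3:] = 0
    w2[:3] = 0
    assert np.allclose(render_dose(w1, inf).values + render_dose(w2, inf).values,
                       full.values)
    with pytest.raises(ValueError):
        render_dose(np.ones(5), inf)


def _tables(vals_a, vals_b):
    keys = [("ctv", "D98"), ("ctv", "D2")]
    return (IndexTable("a", dict(zip(keys, vals_a))),
            IndexTable("b", dict(zip(keys, vals_b))))


def test_delta_report_conventions_and_identities():
    t_pb, t_mc = _tables([79.1, 80.5], [77.5, 81.6])
    same = delta_report(t_pb, t_pb, "doseopt")
    assert all(v == 0 for v in same.percent.values())
    rep = delta_report(t_pb, t_mc, "doseopt")
    assert rep.percent[("ctv", "D98")] == pytest.approx(
        (77.5 - 79.1) / 79.1 * 100.0)
    rep2 = delta_report(t_pb, t_mc, "letopt")
    # swapping conventions negates the delta up to the denominator change
    assert rep2.percent[("ctv", "D98")] == pytest.approx(
        -rep.percent[("ctv", "D98")] * 79.1 / 77.5)
    with pytest.raises(ValueError):
        delta_report(t_pb, t_mc, "other")
    t_zero, _ = _tables([0.0, 1.0], [1.0, 1.0])
    with pytest.raises(ZeroDivisionError):
        delta_report(t_zero, t_mc, "doseopt")


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test


def enumerate_oracle(diffs):
    """Independent 2^n enumeration via itertools over sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s > 0])
          for signs in itertools.product([-1, 1], repeat=len(d))]
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2.0 * min(p_low, p_high))


def test_all_positive_differences_n10():
    d = np.arange(1.0, 11.0)
    w, p = wilcoxon_signed_rank_exact(d)
    assert w == pytest.approx(55.0)
    assert p == pytest.approx(2.0 / 1024.0)


def test_plus_minus_one_gives_p_one():
    w, p = wilcoxon_signed_rank_exact([1.0, -1.0])
    assert p == 1.0


def test_zero_differences_dropped_and_all_zero_error():
    d = np.array([0.0, 0.0, 3.0, -1.0, 2.0])
    w, p = wilcoxon_signed_rank_exact(d)
    w2, p2 = wilcoxon_signed_rank_exact(d[d != 0])
    assert (w, p) == (w2, p2)
    with pytest.raises(ValueError):
        wilcoxon_signed_rank_exact([0.0, 0.0])


@pytest.mark.parametrize("seed,n", [(0, 5), (1, 8), (2, 10), (3, 12)])
def test_matches_exhaustive_enumeration_oracle(seed, n):
    rng = np.random.default_rng(seed)
    d = np.round(rng.normal(0.3, 1.0, n), 2)
    d = np.where(d == 0, 0.11, d)
    w, p = wilcoxon_signed_rank_exact(d)
    w_o, p_o = enumerate_oracle(d)
    assert w == pytest.approx(w_o)
    assert p == pytest.approx(p_o)


def test_close_to_normal_approximation_at_n20():
    rng = np.random.default_rng(7)
    d = rng.normal(0.4, 1.0, 20)
    _, p_exact = wilcoxon_signed_rank_exact(d)
    _, p_norm = scipy_wilcoxon(d, method="approx")
    assert abs(p_exact - p_norm) < 0.02


def test_sample_size_cap():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank_exact(np.ones(25))


def test_index_table_with_let(default_phantom):
    grid, density, ss = default_phantom
    rng = np.random.default_rng(3)
    dose = rng.uniform(70, 80, grid.dims)
    from letimpt import DoseMap

    letd = LETdMap(grid, np.full(grid.dims, 2.5), np.zeros(grid.dims, bool))
    table = index_table("x", DoseMap(grid, dose), ss, letd=letd)
    assert table.indices[("ctv", "D98")] <= table.indices[("ctv", "D2")]
    assert table.let["mean_letd"] == pytest.approx(2.5)
    frame = table.to_frame()
    assert {"structure", "index", "value"} <= set(frame.columns)
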