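"""Statistics layer: CIs, tests, correction, stratification, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conetrack import (assemble_observations, bootstrap_median_diff_test,
                       differential_probability, holm_bonferroni, median_ci,
                       pca_feature_space, rank_sum_test,
                       sliding_window_profile, stratify_by_area)
from conetrack.stats import DEFAULT_AREA_EDGES, profiles_agree


# --------------------------------------------------------------------------
# median CI (notch formula)


def test_median_ci_hand_example():
    """1..9: median 5, IQR 4, n 9 → 5 ± 1.57·4/3 = [2.907, 7.093]."""
    med, lo, hi = median_ci(range(1, 10))
    assert med == pytest.approx(5.0)
    assert lo == pytest.approx(2.907, abs=1e-3)
    assert hi == pytest.approx(7.093, abs=1e-3)


def test_median_ci_constant_and_singleton():
    assert median_ci([4.2] * 10) == pytest.approx((4.2, 4.2, 4.2))
    assert median_ci([3.0]) == pytest.approx((3.0, 3.0, 3.0))


def test_median_ci_empty_rejected():
    with pytest.raises(ValueError):
        median_ci([])


def test_median_ci_width_scales_inverse_sqrt_n():
    """CI half-width follows 1/√n: log-log slope −0.5 ± 0.05."""
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, 100_000)
    ns = [100, 1000, 10_000]
    widths = []
    for n in ns:
        w = []
        for _ in range(40):
            sample = rng.choice(base, size=n)
            _, lo, hi = median_ci(sample)
            w.append(hi - lo)
        widths.append(np.mean(w))
    slope = np.polyfit(np.log(ns), np.log(widths), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.05)


# --------------------------------------------------------------------------
# rank-sum test


def test_rank_sum_identical_samples():
    assert rank_sum_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0


def test_rank_sum_extreme_arrangement_exact():
    """{1,2,3} vs {10,11,12}: the most extreme of C(6,3)=20 splits on
    each side → exact two-sided p = 2/20 = 0.1."""
    assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)


def test_rank_sum_large_shift_tiny_p():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 200)
    b = rng.normal(1, 1, 200)
    assert rank_sum_test(a, b) < 1e-6


def _enumeration_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of all group splits."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(a)
    obs = ranks[:n1].sum()
    sums = [ranks[list(idx)].sum()
            for idx in itertools.combinations(range(len(pooled)), n1)]
    sums = np.asarray(sums)
    mean = sums.mean()
    p = np.mean(np.abs(sums - mean) >= abs(obs - mean) - 1e-12)
    return p


def test_rank_sum_exact_branch_matches_enumeration():
    """Exact branch agrees with full enumeration for two-sample splits
    of 8 distinct values (sizes 3+5 and 4+4)."""
    values = np.array([0.3, 1.1, 2.2, 2.9, 4.1, 5.3, 6.0, 7.7])
    for n1 in (3, 4):
        for idx in itertools.combinations(range(8), n1):
            a = values[list(idx)]
            b = np.delete(values, list(idx))
            assert rank_sum_test(a, b) == pytest.approx(
                _enumeration_oracle(a, b), abs=1e-12)


# --------------------------------------------------------------------------
# bootstrap median-difference test


def test_bootstrap_identical_samples_large_p():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 30)
    p = bootstrap_median_diff_test(x, x.copy(), n_boot=500, seed=0)
    assert p > 0.5


def test_bootstrap_disjoint_samples_small_p():
    a = np.zeros(20)
    b = np.full(20, 10.0)
    p = bootstrap_median_diff_test(a, b, n_boot=1000, seed=0)
    assert p <= 0.01


def test_bootstrap_seed_reproducible():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
    p1 = bootstrap_median_diff_test(a, b, n_boot=500, seed=7)
    p2 = bootstrap_median_diff_test(a, b, n_boot=500, seed=7)
    assert p1 == p2


def test_bootstrap_type_one_error_calibrated():
    """Type-I error at nominal α = 0.05 lies in [0.025, 0.075] over
    1000 simulated null pairs (n = 15 each)."""
    rng = np.random.default_rng(4)
    rejections = 0
    n_sim = 1000
    for i in range(n_sim):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 1, 15)
        p = bootstrap_median_diff_test(a, b, n_boot=400, seed=10_000 + i)
        rejections += p < 0.05
    assert 0.025 <= rejections / n_sim <= 0.075


def test_bootstrap_shift_method_available():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 20), rng.normal(2, 1, 20)
    p = bootstrap_median_diff_test(a, b, n_boot=500, seed=1, method="shift")
    assert p < 0.05


# --------------------------------------------------------------------------
# Holm–Bonferroni


def test_holm_hand_stepdown():
    """{0.01, 0.04, 0.03}: sorted multipliers {3,2,1} then monotone
    enforcement → {0.03, 0.06, 0.06}."""
    adj = holm_bonferroni([0.01, 0.04, 0.03])
    np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])


def test_holm_single_and_saturated():
    np.testing.assert_allclose(holm_bonferroni([0.2]), [0.2])
    np.testing.assert_allclose(holm_bonferroni([1.0, 1.0, 1.0]), 1.0)


def test_holm_invalid_p_rejected():
    with pytest.raises(ValueError):
        holm_bonferroni([0.1, 1.4])


def test_holm_properties():
    rng = np.random.default_rng(6)
    p = rng.uniform(0, 1, 12)
    adj = holm_bonferroni(p)
    assert np.all(adj >= p - 1e-12)           # adjusted ≥ raw
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # order-preserving
    # a fully saturated adjusted set is a fixed point of the step-down
    np.testing.assert_allclose(holm_bonferroni(np.ones_like(p)), 1.0)


# --------------------------------------------------------------------------
# stratification


def _table(rng, n=4000, feature="speed"):
    area = rng.uniform(10, 170, n)
    value = 0.15 - 0.0004 * area + rng.normal(0, 0.01, n)
    return pd.DataFrame({"area_um2": area, feature: value})


def test_area_bin_assignment():
    df = pd.DataFrame({"area_um2": [55.0], "f": [1.0]})
    prof = stratify_by_area(df, "f")
    assert prof.table.bin_lo.iloc[0] == 50.0
    assert prof.table.bin_hi.iloc[0] == 70.0


def test_default_edges_are_eight_bins_10_170():
    assert len(DEFAULT_AREA_EDGES) == 9
    assert DEFAULT_AREA_EDGES[0] == 10.0
    assert DEFAULT_AREA_EDGES[-1] == 170.0
    rng = np.random.default_rng(7)
    prof = stratify_by_area(_table(rng), "speed")
    assert len(prof.table) == 8
    assert (prof.table.ci_low <= prof.table["median"]).all()
    assert (prof.table["median"] <= prof.table.ci_high).all()


def test_uniform_areas_fill_bins_evenly():
    rng = np.random.default_rng(8)
    prof = stratify_by_area(_table(rng, n=8000), "speed")
    n = prof.table.n.to_numpy()
    expected = 8000 / 8
    assert np.all(np.abs(n - expected) < 4 * np.sqrt(expected))


def test_sliding_window_counts():
    """300 rows / window 300 / overlap 220 → 1 window; 380 rows → 2
    windows starting at rows 0 and 80."""
    rng = np.random.default_rng(9)
    df = _table(rng, n=300)
    prof = sliding_window_profile(df, "speed", n_boot=50, seed=0)
    assert prof.table.n.sum() == 300
    df2 = _table(rng, n=380)
    prof2 = sliding_window_profile(df2, "speed", n_boot=50, seed=0)
    assert prof2.table.n.sum() == 2 * 300


def test_sliding_window_requires_enough_rows():
    rng = np.random.default_rng(10)
    with pytest.raises(ValueError):
        sliding_window_profile(_table(rng, n=100), "speed")


def test_window_medians_monotone_for_monotone_feature():
    df = pd.DataFrame({"area_um2": np.linspace(10, 170, 800),
                       "f": np.linspace(1, 2, 800)})
    prof = sliding_window_profile(df, "f", n_boot=100, seed=1)
    med = prof.table["median"].to_numpy()
    assert np.all(np.diff(med) > 0)


def test_stratified_and_sliding_profiles_agree():
    """Fixed-bin and sliding-window profiles of a smooth feature–area
    relationship overlap in CI in every common bin (the binning-artifact
    check)."""
    rng = np.random.default_rng(11)
    df = _table(rng, n=6000)
    fixed = stratify_by_area(df, "speed")
    sliding = sliding_window_profile(df, "speed", n_boot=300, seed=2)
    assert profiles_agree(fixed, sliding)


# --------------------------------------------------------------------------
# differential probabilities


def test_identical_groups_null_differential():
    rng = np.random.default_rng(12)
    x = rng.normal(5, 1, 4000)
    dp = differential_probability(x, x.copy(), n_boot=200, seed=0)
    assert np.abs(dp.table["diff"]).max() == 0.0
    assert (dp.table.boot_p05 <= 0).all() and (dp.table.boot_p95 >= 0).all()


def test_disjoint_groups_sign_structure():
    rng = np.random.default_rng(13)
    a = rng.uniform(0, 1, 2000)
    b = rng.uniform(2, 3, 2000)
    dp = differential_probability(a, b, n_boot=200, seed=0)
    t = dp.table
    assert (t[t.bin_hi <= 1.0]["diff"] >= 0).all()
    assert (t[t.bin_lo >= 2.0]["diff"] <= 0).all()
    assert t["diff"].between(-1, 1).all()


def test_histogram_mass_equals_truncated_fraction():
    """Each group's histogram mass equals (observations ≤ 97th pooled
    percentile) / total — hence ≤ 1."""
    rng = np.random.default_rng(14)
    a = rng.exponential(2, 3000)
    b = rng.exponential(3, 2500)
    dp = differential_probability(a, b, n_boot=100, seed=0)
    hi = np.percentile(np.concatenate([a, b]), 97)
    lo = np.concatenate([a, b]).min()
    exp_a = ((a >= lo) & (a <= hi)).mean()
    assert dp.hist_sum_a <= 1.0 and dp.hist_sum_b <= 1.0
    assert dp.hist_sum_a == pytest.approx(exp_a, abs=2 / len(a))


def test_degenerate_support_rejected():
    with pytest.raises(ValueError):
        differential_probability([1.0] * 50, [1.0] * 50)


def test_front_deficit_crossover_near_2um():
    """When group b lacks comets within 2 μm of the front, the
    differential (a − b) of front distances is positive below ~2 μm and
    negative above — a sign crossover at the configured zone width."""
    from conetrack import SimulationConfig, make_schedule, simulate_sequence
    s = make_schedule(33, 2, 600, 3, 0.211)
    base = dict(background_level=5.0, spot_amplitude=10.0,
                birth_rate_per_um2_s=0.04)
    _, ta = simulate_sequence(SimulationConfig(seed=30, **base), s)
    _, tb = simulate_sequence(
        SimulationConfig(seed=31, front_birth_zone_um=2.0,
                         front_birth_multiplier=0.1, **base), s)
    da = ta.comets.dist_front_um.to_numpy()
    db = tb.comets.dist_front_um.to_numpy()
    dp = differential_probability(da, db, n_value_bins=25, n_boot=200,
                                  seed=0)
    t = dp.table
    below = t[t.bin_hi <= 2.0]["diff"].sum()
    above = t[t.bin_lo >= 2.0]["diff"].sum()
    assert below > 0 > above


# --------------------------------------------------------------------------
# PCA


def test_rank_one_data_concentrates_variance():
    rng = np.random.default_rng(15)
    x = rng.normal(0, 1, 500)
    df = pd.DataFrame({"a": x, "b": 3 * x + 1})
    out = pca_feature_space(df, ["a", "b"])
    assert out["variance_fractions"][0] == pytest.approx(1.0, abs=1e-9)


def test_isotropic_cloud_spreads_variance():
    rng = np.random.default_rng(16)
    df = pd.DataFrame(rng.normal(0, 1, (10_000, 4)),
                      columns=list("abcd"))
    out = pca_feature_space(df, list("abcd"), n_components=4)
    np.testing.assert_allclose(out["variance_fractions"], 0.25, atol=0.02)


def test_dominant_feature_ranks_first():
    """When area drives most variance (correlating with two other
    features), area tops the PC1 loading ranking."""
    rng = np.random.default_rng(17)
    area = rng.uniform(10, 170, 2000)
    df = pd.DataFrame({
        "area_um2": area,
        "perimeter_um": 0.9 * area + rng.normal(0, 4, 2000),
        "speed": -0.001 * area + rng.normal(0, 0.04, 2000),
        "noise": rng.normal(0, 1, 2000),
    })
    out = pca_feature_space(df, list(df.columns))
    assert out["ranking"][0] in ("area_um2", "perimeter_um")
    assert abs(out["loadings"].loc["area_um2", "PC1"]) > \
        abs(out["loadings"].loc["noise", "PC1"])


def test_constant_feature_dropped():
    rng = np.random.default_rng(18)
    df = pd.DataFrame({"a": rng.normal(size=100),
                       "b": rng.normal(size=100),
                       "c": np.ones(100)})
    out = pca_feature_space(df, ["a", "b", "c"])
    assert out["features"] == ["a", "b"]


# --------------------------------------------------------------------------
# observation assembly


def _toy_tables():
    cones = pd.DataFrame({
        "cone_id": [0, 0], "frame_global": [0, 1], "t_s": [0.0, 2.0],
        "burst": [0, 0], "area_um2": [50.0, 50.0],
    })
    comets = pd.DataFrame({
        "cone_id": [0] * 5, "track_id": [0, 1, 2, 3, 4],
        "frame_global": [0] * 5,
        "speed_um_s": [0.1, 0.12, 0.08, np.nan, 0.2],
        "dist_front_um": [1, 2, 3, 4, 5.0],
        "dist_midline_um": [1, 1, 1, 1, 1.0],
    })
    return cones, comets


def test_assembly_counts_and_density():
    cones, comets = _toy_tables()
    obs = assemble_observations(cones, comets)
    row0 = obs.cones[obs.cones.frame_global == 0].iloc[0]
    assert row0.comet_number == 5
    assert row0.comet_density_per_um2 == pytest.approx(0.1)
    row1 = obs.cones[obs.cones.frame_global == 1].iloc[0]
    assert row1.comet_number == 0
    assert row1.comet_density_per_um2 == 0.0
    assert np.isnan(row1.median_comet_speed_um_s)


def test_orphan_comets_rejected():
    cones, comets = _toy_tables()
    comets.loc[2, "frame_global"] = 99
    with pytest.raises(ValueError, match="orphan"):
        assemble_observations(cones, comets)
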