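"""Multiscale statistics: observation tables, CIs, tests, stratification.

Implements the statistical layer of the analysis: the two-level
observation hierarchy (time-resolved growth-cone records and
time-resolved comet records), notch-style median confidence intervals,
rank-sum and bootstrap hypothesis tests with Holm–Bonferroni correction,
growth-cone-area stratification (fixed 20-μm² bins and sliding-window
bootstrap re-aggregation), differential probability distributions with
bootstrap envelopes, and PCA of the growth-cone feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationTables",
    "StratifiedProfile",
    "DifferentialProbability",
    "assemble_observations",
    "median_ci",
    "rank_sum_test",
    "bootstrap_median_diff_test",
    "holm_bonferroni",
    "stratify_by_area",
    "sliding_window_profile",
    "differential_probability",
    "pca_feature_space",
    "DEFAULT_AREA_EDGES",
]

#: Canonical growth-cone-area stratification: 8 bins of 20 μm², 10–170 μm².
DEFAULT_AREA_EDGES = np.arange(10.0, 171.0, 20.0)


# --------------------------------------------------------------------------
# containers


@dataclass
class ObservationTables:
    """The two-level observation hierarchy.

    ``cones``: one row per growth cone per frame (time, morphology,
    comet aggregates, behavior and group labels). ``comets``: one row
    per comet per frame (instantaneous speed, distances, angle, class),
    each referencing its growth-cone row by (cone_id, frame_global).
    """

    cones: pd.DataFrame
    comets: pd.DataFrame


@dataclass
class StratifiedProfile:
    """Per-area-bin medians with confidence intervals for one feature."""

    feature: str
    table: pd.DataFrame  # bin_lo, bin_hi, n, median, ci_low, ci_high
    group: str = ""


@dataclass
class DifferentialProbability:
    """Bin-wise difference of two normalized feature histograms.

    ``table`` has one row per value bin: bin edges, the observed
    differential probability (P_a − P_b), its bootstrap median and the
    5th/95th percentile envelope. ``hist_sum_a``/``b`` record each
    group's total histogram mass (≤ 1 after 97th-percentile truncation).
    """

    feature: str
    table: pd.DataFrame
    hist_sum_a: float
    hist_sum_b: float
    area_bin: tuple[float, float] | None = None


# --------------------------------------------------------------------------
# elementary statistics


def median_ci(values) -> tuple[float, float, float]:
    """Median with the notch-style 95% CI: q2 ± 1.57·IQR/√n.

    q2 is the median, IQR the 75th−25th percentile difference and n the
    number of observations (the boxplot-notch formula).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("median_ci requires at least one observation")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    half = 1.57 * (q3 - q1) / np.sqrt(v.size)
    return float(q2), float(q2 - half), float(q2 + half)


def rank_sum_test(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration of the permutation distribution for small
    (≤ 20 per group), tie-free samples; tie-corrected normal
    approximation with continuity correction otherwise. Two samples
    whose pooled values are all identical give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 20 and b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method=method).pvalue)


def bootstrap_median_diff_test(
    sample_a,
    sample_b,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "shift",
) -> float:
    """Two-sided bootstrap p-value for a difference of medians.

    The observed statistic is median(a) − median(b). Under the default
    percentile-shift null each group is resampled with replacement from
    itself after both are centered on the pooled median, which keeps
    each group's own dispersion under the null; p is the fraction of
    null |statistic| ≥ |observed| with a +1/(n_boot+1) continuity term.
    ``method="pooled"`` instead resamples both groups from the pooled
    values (group sizes preserved); that null is ill-calibrated when
    the two groups have very different dispersions or multimodal
    support.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    observed = np.median(a) - np.median(b)
    if method == "pooled":
        pooled = np.concatenate([a, b])
        ra = rng.choice(pooled, size=(n_boot, a.size), replace=True)
        rb = rng.choice(pooled, size=(n_boot, b.size), replace=True)
    elif method == "shift":
        pooled_med = np.median(np.concatenate([a, b]))
        a0 = a - np.median(a) + pooled_med
        b0 = b - np.median(b) + pooled_med
        ra = rng.choice(a0, size=(n_boot, a.size), replace=True)
        rb = rng.choice(b0, size=(n_boot, b.size), replace=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    null = np.median(ra, axis=1) - np.median(rb, axis=1)
    exceed = np.count_nonzero(np.abs(null) >= abs(observed))
    return float((exceed + 1) / (n_boot + 1))


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# --------------------------------------------------------------------------
# observation assembly


def assemble_observations(
    cone_frames: pd.DataFrame,
    comet_frames: pd.DataFrame,
    behaviors: pd.DataFrame | None = None,
    group: str = "",
) -> ObservationTables:
    """Join per-frame cone geometry, comet records and behavior labels.

    ``cone_frames`` needs columns (cone_id, frame_global, t_s,
    area_um2, ...scalar morphology); ``comet_frames`` needs (cone_id,
    track_id, frame_global, speed_um_s, dist_front_um, dist_midline_um,
    path_angle_deg, direction_class, burst). Per-frame comet aggregates
    (count, density, median speed and distances) are attached to the
    cone rows; behavior labels are joined by burst. Comet rows whose
    (cone_id, frame_global) has no cone row raise a ValueError.
    """
    cones = cone_frames.copy()
    comets = comet_frames.copy()
    key = ["cone_id", "frame_global"]
    missing = comets.merge(cones[key].drop_duplicates(), on=key,
                           how="left", indicator=True)
    orphans = missing[missing["_merge"] == "left_only"]
    if len(orphans):
        ids = orphans[key].drop_duplicates().to_records(index=False).tolist()
        raise ValueError(f"orphan comet rows for (cone, frame): {ids[:10]}")

    agg = comets.groupby(key).agg(
        comet_number=("track_id", "nunique"),
        median_comet_speed_um_s=("speed_um_s", "median"),
        median_dist_front_um=("dist_front_um", "median"),
        median_dist_midline_um=("dist_midline_um", "median"),
    ).reset_index()
    cones = cones.merge(agg, on=key, how="left")
    cones["comet_number"] = cones["comet_number"].fillna(0).astype(int)
    cones["comet_density_per_um2"] = cones["comet_number"] / cones["area_um2"]
    # zero-comet frames keep NaN speed/distance aggregates by design

    if behaviors is not None and len(behaviors):
        lab = behaviors.rename(columns={"burst_a": "burst"})[
            ["cone_id", "burst", "label"]]
        if "burst" in cones.columns:
            cones = cones.merge(lab, on=["cone_id", "burst"], how="left")
            cones = cones.rename(columns={"label": "behavior"})
    cones["group"] = group
    comets["group"] = group
    return ObservationTables(cones=cones, comets=comets)


# --------------------------------------------------------------------------
# stratification


def stratify_by_area(
    table: pd.DataFrame,
    feature: str,
    edges=DEFAULT_AREA_EDGES,
    area_col: str = "area_um2",
    group: str = "",
) -> StratifiedProfile:
    """Median ± CI of a feature per half-open growth-cone-area bin.

    Observations outside every bin are excluded (count logged); empty
    bins are omitted.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be ascending with >= 2 values")
    if feature not in table.columns:
        raise ValueError(f"feature {feature!r} not in table")
    df = table.dropna(subset=[feature, area_col])
    outside = ((df[area_col] < edges[0]) | (df[area_col] >= edges[-1])).sum()
    if outside:
        logger.info("%d observations outside area bins excluded", outside)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = df[(df[area_col] >= lo) & (df[area_col] < hi)]
        if sel.empty:
            continue
        med, ci_lo, ci_hi = median_ci(sel[feature].to_numpy())
        rows.append((lo, hi, len(sel), med, ci_lo, ci_hi))
    out = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n", "median",
                                      "ci_low", "ci_high"])
    return StratifiedProfile(feature=feature, table=out, group=group)


def sliding_window_profile(
    table: pd.DataFrame,
    feature: str,
    window_size: int = 300,
    overlap: int = 220,
    n_boot: int = 1000,
    seed: int | None = None,
    edges=DEFAULT_AREA_EDGES,
    area_col: str = "area_um2",
    group: str = "",
) -> StratifiedProfile:
    """Sliding-window bootstrap profile re-aggregated into area bins.

    Rows are sorted by area; windows of ``window_size`` rows advance by
    ``window_size − overlap`` rows. Per window, ``n_boot`` bootstrap
    medians of the feature are drawn; each window is then assigned to
    the area bin containing its median area, and per bin the pooled
    bootstrap medians give the median and 2.5/97.5 percentile CI. This
    continuous sampling is the binning-artifact check for
    :func:`stratify_by_area`.
    """
    if not 0 <= overlap < window_size:
        raise ValueError("need 0 <= overlap < window_size")
    df = table.dropna(subset=[feature, area_col]).sort_values(
        area_col, kind="mergesort").reset_index(drop=True)
    if len(df) < window_size:
        raise ValueError(
            f"table has {len(df)} rows; need at least window_size={window_size}")
    rng = np.random.default_rng(seed)
    step = window_size - overlap
    edges = np.asarray(edges, dtype=float)
    starts = range(0, len(df) - window_size + 1, step)
    win_area, win_boots = [], []
    vals = df[feature].to_numpy()
    areas = df[area_col].to_numpy()
    for s in starts:
        w = vals[s:s + window_size]
        idx = rng.integers(0, window_size, size=(n_boot, window_size))
        win_boots.append(np.median(w[idx], axis=1))
        win_area.append(np.median(areas[s:s + window_size]))
    win_area = np.asarray(win_area)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = [b for a, b in zip(win_area, win_boots) if lo <= a < hi]
        if not sel:
            continue
        pool = np.concatenate(sel)
        rows.append((lo, hi, len(sel) * window_size, float(np.median(pool)),
                     float(np.percentile(pool, 2.5)),
                     float(np.percentile(pool, 97.5))))
    out = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n", "median",
                                      "ci_low", "ci_high"])
    return StratifiedProfile(feature=feature, table=out, group=group)


def profiles_agree(p1: StratifiedProfile, p2: StratifiedProfile) -> bool:
    """CI-overlap agreement of two profiles in every common area bin."""
    merged = p1.table.merge(p2.table, on=["bin_lo", "bin_hi"],
                            suffixes=("_1", "_2"))
    if merged.empty:
        return False
    ok = (merged["ci_low_1"] <= merged["ci_high_2"]) & \
         (merged["ci_low_2"] <= merged["ci_high_1"])
    return bool(ok.all())


# --------------------------------------------------------------------------
# differential probabilities


def differential_probability(
    values_a,
    values_b,
    n_value_bins: int = 25,
    n_boot: int = 1000,
    seed: int | None = None,
    feature: str = "",
    area_bin: tuple[float, float] | None = None,
) -> DifferentialProbability:
    """Differential probability distribution of a feature between groups.

    Common value-bin edges run from the pooled minimum to the pooled
    97th percentile (equal bin number and width for both groups). Each
    group's histogram is normalized by its total observation count, so
    the histogram mass equals the fraction of observations at or below
    the 97th-percentile cut (≤ 1). The differential is P_a − P_b per
    value bin; each group is resampled with replacement ``n_boot`` times
    to give the bootstrap median and the 5th/95th percentile envelopes.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    lo, hi = float(pooled.min()), float(np.percentile(pooled, 97))
    if hi <= lo:
        raise ValueError("pooled 97th percentile <= pooled minimum")
    edges = np.linspace(lo, hi, n_value_bins + 1)

    def prob_hist(x: np.ndarray) -> np.ndarray:
        h, _ = np.histogram(x, bins=edges)
        return h / x.size

    pa, pb = prob_hist(a), prob_hist(b)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_value_bins))
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        boots[i] = prob_hist(ra) - prob_hist(rb)
    table = pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "diff": pa - pb,
        "boot_median": np.median(boots, axis=0),
        "boot_p05": np.percentile(boots, 5, axis=0),
        "boot_p95": np.percentile(boots, 95, axis=0),
    })
    return DifferentialProbability(
        feature=feature, table=table, hist_sum_a=float(pa.sum()),
        hist_sum_b=float(pb.sum()), area_bin=area_bin)


# --------------------------------------------------------------------------
# PCA feature space


def pca_feature_space(
    table: pd.DataFrame,
    features: list[str],
    n_components: int = 2,
) -> dict:
    """Standardized PCA of the growth-cone feature space.

    Features are z-scored before decomposition; constant features are
    dropped with a warning; rows with missing values in the remaining
    features are dropped. Returns per-observation scores, per-feature
    loadings, variance fractions and features ranked by |loading| on
    PC1.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    keep = []
    for f in features:
        if f not in table.columns:
            raise ValueError(f"feature {f!r} not in table")
        col = table[f].dropna()
        if col.nunique() <= 1:
            logger.warning("constant feature %r dropped from PCA", f)
            continue
        keep.append(f)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant features")
    data = table[keep].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete observations")
    x = StandardScaler().fit_transform(data.to_numpy(dtype=float))
    k = min(n_components, len(keep))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    loadings = pd.DataFrame(pca.components_.T, index=keep,
                            columns=[f"PC{i+1}" for i in range(k)])
    ranking = loadings["PC1"].abs().sort_values(ascending=False).index.tolist()
    return {
        "scores": pd.DataFrame(scores, index=data.index,
                               columns=[f"PC{i+1}" for i in range(k)]),
        "loadings": loadings,
        "variance_fractions": pca.explained_variance_ratio_,
        "ranking": ranking,
        "features": keep,
    }
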