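"""Recovery and calibration benchmarks for the pipeline's statistics.

Each function re-runs a piece of the package against synthetic data with
known truth (or against an independent oracle) and returns the measured
rate or error.  They are used by the validation suite and the acceptance
script; sizes follow the package's standard benchmark conditions: 5 cohorts
of n = 200 for core recovery, 100 small cohorts for the percentile oracle,
1000 replicates for the two type-I calibrations, 50 cohorts of n = 300 for
the planted age effect, and 20 replicates of the 200-taxon planted-effect
benchmark for differential abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._dip import dip_statistic
from ._dip_oracle import exact_dip
from .community_stats import DistanceMatrix, PermutationConfig, metric_vs_age, permanova
from .core_reference import build_reference, core_metrics, extract_core
from .diff_abundance import bh_adjust, da_filter, fit_da, tss_log
from .synthetic_data import da_benchmark_spec, paperlike_spec, simulate_cohort
from .table_io import CountTable, RelAbundTable, filter_low_depth, to_relative_abundance

__all__ = [
    "core_recovery_rate",
    "percentile_oracle_max_err",
    "dip_small_n_battery_max_err",
    "dip_type_i_error",
    "permanova_exact_two_group_p",
    "permanova_type_i_error",
    "permanova_vs_anova_max_err",
    "bh_hand_check_max_err",
    "age_effect_detection_rate",
    "da_planted_effect_benchmark",
    "stochastic_determinism_ok",
]


def _manual_percentile(sorted_vals: np.ndarray, q_pct: float) -> float:
    # hand-written linear interpolation between order statistics
    n = len(sorted_vals)
    if n == 1:
        return float(sorted_vals[0])
    h = (n - 1) * (q_pct / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return float(sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo]))


def core_recovery_rate(seed: int, n_cohorts: int = 5, n_samples: int = 200) -> float:
    """Share of synthetic cohorts whose planted core is recovered exactly."""
    hits = 0
    for k in range(n_cohorts):
        spec = paperlike_spec(seed + k, n_samples=n_samples)
        table, _, _ = simulate_cohort(spec)
        table, _ = filter_low_depth(table)
        planted = {t.label for t in spec.taxa if t.is_core_truth}
        hits += set(extract_core(table)) == planted
    return hits / n_cohorts


def percentile_oracle_max_err(seed: int, n_cohorts: int = 100) -> float:
    """Max |reference percentile - hand interpolation oracle| over cohorts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cohorts):
        n_taxa = int(rng.integers(3, 7))
        n_samples = int(rng.integers(6, 25))
        counts = rng.integers(0, 4000, size=(n_taxa, n_samples))
        counts[0] += 500  # keep column sums positive and one taxon common
        df = pd.DataFrame(
            counts,
            index=pd.Index([f"g{i}" for i in range(n_taxa)], name="taxon_id"),
            columns=[f"s{j}" for j in range(n_samples)],
        )
        table = CountTable(df)
        rel = to_relative_abundance(table)
        core = list(df.index)
        ref = build_reference(table, rel, core)
        for g in core:
            mask = (df.loc[g] >= 25).to_numpy()
            vals = np.sort(100.0 * rel.df.loc[g].to_numpy()[mask])
            if vals.size == 0:
                continue
            r = ref.ranges[g]
            for q, got in [(2.5, r.p2_5), (10, r.p10), (50, r.median),
                           (90, r.p90), (97.5, r.p97_5)]:
                worst = max(worst, abs(got - _manual_percentile(vals, q)))
    return worst


def dip_small_n_battery_max_err(seed: int, n_random: int = 12) -> float:
    """Max |fast dip - LP oracle| over a small-n battery (n <= 8)."""
    rng = np.random.default_rng(seed)
    cases = [
        [0, 0, 0, 1, 1, 1],
        [0, 1, 2, 3],
        [1, 3, 3, 3],
        [0, 0.001, 1, 1.001],
        [0, 0, 1, 1, 2, 2],
        [0.1, 0.2, 0.3, 5.0, 5.1, 5.2, 5.3],
    ]
    for i in range(n_random):
        n = int(rng.integers(4, 9))
        if i % 3 == 0:
            cases.append(rng.integers(0, 4, n).astype(float).tolist())
        elif i % 3 == 1:
            cases.append(rng.uniform(0, 1, n).tolist())
        else:
            half = n // 2
            cases.append(
                np.concatenate(
                    [rng.normal(0, 0.2, half), rng.normal(3, 0.2, n - half)]
                ).tolist()
            )
    return max(abs(dip_statistic(c) - exact_dip(c)) for c in cases)


def dip_type_i_error(
    seed: int, n_reps: int = 1000, n: int = 50, n_null: int = 199,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the Monte-Carlo dip test on uniform null samples."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        d_obs = dip_statistic(rng.random(n))
        count = sum(
            dip_statistic(rng.random(n)) >= d_obs - 1e-15 for _ in range(n_null)
        )
        p = (count + 1) / (n_null + 1)
        rejections += p <= alpha
    return rejections / n_reps


def permanova_exact_two_group_p() -> float:
    """Exact enumeration p for two maximally separated identical-point
    groups of three (only the true labeling and its mirror reach the
    extreme pseudo-F: p = 2/20 = 0.1)."""
    pts = np.array([[0.0, 0.0]] * 3 + [[100.0, 0.0]] * 3)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = list("abcdef")
    dm = DistanceMatrix(ids, d)
    groups = pd.Series(list("xxxyyy"), index=ids)
    return permanova(dm, groups, permutations="exact")[0].p


def permanova_type_i_error(
    seed: int, n_reps: int = 1000, n: int = 20, n_perm: int = 99,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of PERMANOVA on group-free Bray-Curtis data."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    labels = pd.Series(["a"] * (n // 2) + ["b"] * (n - n // 2), index=ids)
    rejections = 0
    for k in range(n_reps):
        rel = rng.dirichlet(np.ones(4), size=n)
        diff = np.abs(rel[:, None, :] - rel[None, :, :]).sum(-1)
        denom = rel.sum(1)[:, None] + rel.sum(1)[None, :]
        dm = DistanceMatrix(ids, diff / denom)
        cfg = PermutationConfig(n_perm, int(rng.integers(2**31)))
        p = permanova(dm, labels, cfg)[0].p
        rejections += p <= alpha
    return rejections / n_reps


def permanova_vs_anova_max_err(seed: int, n_reps: int = 20) -> float:
    """Max |pseudo-F - classical one-way ANOVA F| for univariate Euclidean
    data (they coincide exactly in this limit)."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        sizes = rng.integers(4, 9, size=3)
        y = np.concatenate(
            [rng.normal(i * rng.uniform(0, 2), 1, s) for i, s in enumerate(sizes)]
        )
        labels = np.repeat(["a", "b", "c"], sizes)
        ids = [f"s{i}" for i in range(len(y))]
        dm = DistanceMatrix(ids, np.abs(y[:, None] - y[None, :]))
        res = permanova(dm, pd.Series(labels, index=ids), PermutationConfig(9, 0))[0]
        f_classic = f_oneway(*[y[labels == g] for g in "abc"]).statistic
        worst = max(worst, abs(res.statistic - f_classic))
    return worst


def bh_hand_check_max_err() -> float:
    """Max deviation from the two hand-computed step-up vectors."""
    err1 = np.abs(
        bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]) - np.full(5, 0.05)
    ).max()
    err2 = np.abs(bh_adjust([0.005, 0.04, 0.2]) - np.array([0.015, 0.06, 0.2])).max()
    return float(max(err1, err2))


def age_effect_detection_rate(
    seed: int, n_cohorts: int = 50, n_samples: int = 300
) -> float:
    """Share of cohorts where the planted negative age effect on core-taxa-
    present is detected (negative OLS slope, p < 0.05)."""
    hits = 0
    for k in range(n_cohorts):
        table, meta, _ = simulate_cohort(paperlike_spec(seed + k, n_samples=n_samples))
        table, _ = filter_low_depth(table)
        rel = to_relative_abundance(table)
        core = extract_core(table)
        cm = core_metrics(table, rel, core)
        res = metric_vs_age(
            cm["core_taxa_present_pct"], meta.loc[cm.index, "age_years"]
        )
        hits += (res.statistic < 0) and (res.p < 0.05)
    return hits / n_cohorts


def da_planted_effect_benchmark(
    seed: int, n_reps: int = 20, q_cut: float = 0.05
) -> tuple[float, float]:
    """(mean sensitivity, mean observed FDR) of the differential-abundance
    stage on the 200-taxon planted-effect benchmark at q <= 0.05."""
    sens, fdr = [], []
    for k in range(n_reps):
        spec = da_benchmark_spec(seed + k)
        table, meta, _ = simulate_cohort(spec)
        rel = to_relative_abundance(table)
        kept = da_filter(rel)
        sub = rel.df.loc[kept]
        transformed = tss_log(RelAbundTable(sub / sub.sum(axis=0)))
        meta = meta.copy()
        meta["diet_dry"] = meta["diet_dry"].astype(float)
        res = fit_da(transformed, meta, ["diet_dry"])
        truth_pos = {t.label for t in spec.taxa if t.abundance_effects}
        called = set(res.loc[res["q"] <= q_cut, "taxon"])
        tp = len(called & truth_pos)
        sens.append(tp / len(truth_pos))
        fdr.append(len(called - truth_pos) / max(len(called), 1))
    return float(np.mean(sens)), float(np.mean(fdr))


def stochastic_determinism_ok(seed: int) -> bool:
    """Same seed twice => identical simulation, PERMANOVA p and dip p."""
    t1, _, _ = simulate_cohort(paperlike_spec(seed, n_samples=30))
    t2, _, _ = simulate_cohort(paperlike_spec(seed, n_samples=30))
    if not np.array_equal(t1.counts, t2.counts):
        return False
    rng = np.random.default_rng(seed)
    rel = rng.dirichlet(np.ones(5), size=12)
    ids = [f"s{i}" for i in range(12)]
    diff = np.abs(rel[:, None, :] - rel[None, :, :]).sum(-1)
    dm = DistanceMatrix(ids, diff / (rel.sum(1)[:, None] + rel.sum(1)[None, :]))
    groups = pd.Series(["a"] * 6 + ["b"] * 6, index=ids)
    p1 = permanova(dm, groups, PermutationConfig(99, seed))[0].p
    p2 = permanova(dm, groups, PermutationConfig(99, seed))[0].p
    x = rng.normal(size=60)
    from .community_stats import dip_test

    d1 = dip_test(x, PermutationConfig(99, seed)).p
    d2 = dip_test(x, PermutationConfig(99, seed)).p
    return p1 == p2 and d1 == d2
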