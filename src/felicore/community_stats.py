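"""Community statistics implemented from first principles.

Alpha diversity (observed richness, Shannon, Gini-Simpson, Pielou's
evenness), Bray-Curtis dissimilarity, principal coordinate analysis,
PERMANOVA (McArdle-Anderson pseudo-F on the Gower-centered inner-product
matrix, categorical or continuous predictors, sequential attribution),
PERMDISP (distances to group centroids in the real-axis PCoA embedding),
pairwise PERMANOVA with Benjamini-Hochberg adjustment, Hartigan's dip test
with a Monte-Carlo uniform null, and ordinary least-squares trend models
for per-sample metrics against age.

Permutation p-values use the (exceedances + 1)/(permutations + 1) rule so a
permutation p can never be exactly zero; every stochastic routine takes an
explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._dip import dip_statistic
from .diff_abundance import bh_adjust

__all__ = [
    "DistanceMatrix",
    "PermutationConfig",
    "TestResult",
    "observed_richness",
    "shannon",
    "gini_simpson",
    "pielou",
    "alpha_diversity_table",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
    "permdisp",
    "pairwise_permanova",
    "dip_statistic",
    "dip_test",
    "metric_vs_age",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(d < 0):
            raise ValueError("negative distances")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "sample_id"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", lineterminator="\n")


@dataclass
class PermutationConfig:
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class TestResult:
    """One permutation (or OLS) test: statistic, effect size, p-value."""

    name: str
    statistic: float
    p: float
    r2: float = float("nan")
    df: tuple[int, int] | None = None
    n_permutations: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1 or math.isnan(self.p)):
            raise ValueError(f"p-value out of (0, 1]: {self.p}")


# ---------------------------------------------------------------------------
# alpha diversity


def observed_richness(counts) -> int:
    """Number of taxa with a nonzero count in one sample."""
    return int(np.count_nonzero(np.asarray(counts)))


def _check_props(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return p


def shannon(props) -> float:
    """Shannon entropy H = -sum p ln p (natural log), zeros skipped."""
    p = _check_props(props)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def gini_simpson(props) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    p = _check_props(props)
    return float(1.0 - (p**2).sum())


def pielou(props) -> float:
    """Pielou's evenness H / ln S; NaN (undefined) for a single taxon."""
    p = _check_props(props)
    s = observed_richness(p)
    if s < 2:
        return float("nan")
    return shannon(p) / math.log(s)


def alpha_diversity_table(counts_df: pd.DataFrame) -> pd.DataFrame:
    """All four alpha metrics per sample from a taxa-x-samples count table."""
    rows = {}
    for s in counts_df.columns:
        c = counts_df[s].to_numpy(dtype=float)
        tot = c.sum()
        if tot == 0:
            raise ValueError(f"sample {s!r} has zero total reads")
        p = c / tot
        rows[s] = {
            "observed_richness": observed_richness(c),
            "shannon": shannon(p),
            "gini_simpson": gini_simpson(p),
            "pielou": pielou(p),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Bray-Curtis and PCoA


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        warnings.warn("Bray-Curtis between two all-zero samples set to 0", stacklevel=2)
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(rel_df: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Bray-Curtis from a taxa-x-samples relative-abundance table."""
    x = rel_df.to_numpy(dtype=float).T  # samples x taxa
    sums = x.sum(axis=1)
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    denom = sums[:, None] + sums[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, diff / np.where(denom == 0, 1.0, denom), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(rel_df.columns), d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the double-centered Gower matrix; axes are
    ordered by decreasing eigenvalue and only positive-eigenvalue axes
    contribute coordinates.  Negative eigenvalues (non-Euclidean
    distances) are returned for inspection but excluded; no Cailliez or
    Lingoes correction is applied.
    """
    if dm.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    g = _gower_center(dm.values)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    if (evals < -tol).any():
        warnings.warn(
            f"PCoA: {int((evals < -tol).sum())} negative eigenvalues "
            f"(min {evals.min():.3g}) excluded from coordinates",
            stacklevel=2,
        )
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dm.ids, columns=cols), evals


# ---------------------------------------------------------------------------
# PERMANOVA


def _model_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    col = design[term]
    if col.isna().any():
        raise ValueError(f"predictor {term!r} has missing values")
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"predictor {term!r} is constant")
        # drop-first dummy coding
        return np.column_stack([(col == lv).to_numpy(float) for lv in levels[1:]])
    x = col.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {term!r} is constant")
    return x[:, None]


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame | pd.Series,
    cfg: PermutationConfig | None = None,
    permutations: int | str | None = None,
) -> list[TestResult]:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F for each term follows the hat-matrix partition of the
    Gower-centered inner-product matrix G: with H the hat matrix of the
    model up to and including the term (sequential, Type I) and m its added
    degrees of freedom, F = (tr(H G H)/m) / (tr((I-H_full) G (I-H_full)) /
    (n - m_full - 1)) and R^2 = SS_term / tr(G).  Significance comes from
    permuting sample labels of the distance matrix; ``permutations="exact"``
    enumerates all n! relabelings (small n only) and divides the exceedance
    count by the total, identity included.
    """
    cfg = cfg or PermutationConfig()
    if isinstance(design, pd.Series):
        design = design.to_frame(design.name or "group")
    if list(design.index) != list(dm.ids):
        design = design.loc[dm.ids]
    n = dm.n
    terms = list(design.columns)
    g = _gower_center(dm.values)
    tr_g = float(np.trace(g))

    blocks = [_model_columns(design, t) for t in terms]
    dfs = [b.shape[1] for b in blocks]
    ones = np.ones((n, 1))
    hats = []  # cumulative hat matrices including intercept
    x = ones
    for b in blocks:
        x = np.column_stack([x, b])
        hats.append(_hat(x))
    m_full = sum(dfs)
    df_res = n - m_full - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    h_full = hats[-1]
    resid_proj = np.eye(n) - h_full

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = []
        prev = 0.0
        for h in hats:
            cur = float((h * gmat).sum())  # tr(H G)
            ss.append(cur - prev)
            prev = cur
        ss_res = float(np.trace(resid_proj @ gmat @ resid_proj))
        return np.array(ss), ss_res

    ss_obs, ss_res_obs = term_stats(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    if permutations == "exact":
        if math.factorial(n) > 50000:
            raise ValueError("exact enumeration infeasible for this n")
        perms = np.array(list(itertools.permutations(range(n))))
        count = np.zeros(len(terms))
        for p in perms:
            gp = g[np.ix_(p, p)]
            ss_p, ss_res_p = term_stats(gp)
            f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
            count += f_p >= f_obs - 1e-12
        pvals = count / len(perms)
        n_perm = len(perms)
    else:
        n_perm = cfg.n_permutations if permutations is None else int(permutations)
        rng = np.random.default_rng(cfg.seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            p = rng.permutation(n)
            gp = g[np.ix_(p, p)]
            ss_p, ss_res_p = term_stats(gp)
            f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
            count += f_p >= f_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)

    return [
        TestResult(
            name=f"PERMANOVA[{t}]",
            statistic=float(f_obs[i]),
            p=float(pvals[i]),
            r2=float(ss_obs[i] / tr_g),
            df=(dfs[i], df_res),
            n_permutations=n_perm,
            seed=cfg.seed,
        )
        for i, t in enumerate(terms)
    ]


# ---------------------------------------------------------------------------
# PERMDISP


def _centroid_distances(coords: np.ndarray, groups: np.ndarray) -> np.ndarray:
    z = np.empty(coords.shape[0])
    for g in np.unique(groups):
        mask = groups == g
        centroid = coords[mask].mean(axis=0)
        z[mask] = np.sqrt(((coords[mask] - centroid) ** 2).sum(axis=1))
    return z


def _anova_f(z: np.ndarray, groups: np.ndarray) -> float:
    grand = z.mean()
    ss_b = ss_w = 0.0
    k = 0
    for g in np.unique(groups):
        zg = z[groups == g]
        ss_b += len(zg) * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
        k += 1
    df1, df2 = k - 1, len(z) - k
    if ss_w == 0:
        return float("inf") if ss_b > 0 else 0.0
    return (ss_b / df1) / (ss_w / df2)


def permdisp(
    dm: DistanceMatrix,
    groups: pd.Series | Sequence[str],
    cfg: PermutationConfig | None = None,
    use_medians: bool = False,
) -> TestResult:
    """Homogeneity-of-dispersion test (distances to group centroids).

    Samples are embedded on the real PCoA axes; each sample's distance to
    its group centroid (or coordinate-wise median with ``use_medians``) is
    the dispersion score; a one-way ANOVA F on the scores is assessed by
    permuting group labels of the fixed scores' samples.
    """
    cfg = cfg or PermutationConfig()
    groups = np.asarray(pd.Series(groups).reindex(dm.ids).to_numpy()
                        if isinstance(groups, pd.Series) else list(groups))
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMDISP needs at least two groups")
    if counts.min() < 2:
        raise ValueError(f"singleton group {uniq[counts.argmin()]!r}")
    coords, _ = pcoa(dm)
    c = coords.to_numpy()

    def scores(gr: np.ndarray) -> np.ndarray:
        if use_medians:
            z = np.empty(len(gr))
            for g in np.unique(gr):
                mask = gr == g
                med = np.median(c[mask], axis=0)
                z[mask] = np.sqrt(((c[mask] - med) ** 2).sum(axis=1))
            return z
        return _centroid_distances(c, gr)

    z = scores(groups)
    f_obs = _anova_f(z, groups)
    rng = np.random.default_rng(cfg.seed)
    count = 0
    for _ in range(cfg.n_permutations):
        gp = groups[rng.permutation(len(groups))]
        if _anova_f(z, gp) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (cfg.n_permutations + 1)
    return TestResult(
        name="PERMDISP",
        statistic=float(f_obs),
        p=float(p),
        df=(len(uniq) - 1, len(groups) - len(uniq)),
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    cfg: PermutationConfig | None = None,
) -> pd.DataFrame:
    """PERMANOVA on every group pair with Benjamini-Hochberg adjustment."""
    cfg = cfg or PermutationConfig()
    groups = groups.reindex(dm.ids)
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in itertools.combinations(uniq, 2):
        ids = [s for s in dm.ids if groups[s] in (a, b)]
        sub = dm.submatrix(ids)
        res = permanova(sub, groups.loc[ids].astype(str), cfg)[0]
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "F": res.statistic,
                "R2": res.r2,
                "p": res.p,
                "n": len(ids),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# dip test


def dip_test(values, cfg: PermutationConfig | None = None) -> TestResult:
    """Monte-Carlo dip test of unimodality against the uniform null.

    The p-value is the share of ``n_permutations`` uniform(0,1) samples of
    the same size whose dip reaches the observed one, with the +1
    correction.  The uniform is the asymptotically least favorable
    unimodal null, so the test is conservative for peaked unimodal data.
    """
    cfg = cfg or PermutationConfig()
    x = np.asarray(values, dtype=float)
    d_obs = dip_statistic(x)
    rng = np.random.default_rng(cfg.seed)
    n = x.size
    count = 0
    for _ in range(cfg.n_permutations):
        if dip_statistic(rng.random(n)) >= d_obs - 1e-15:
            count += 1
    p = (count + 1) / (cfg.n_permutations + 1)
    return TestResult(
        name="dip",
        statistic=float(d_obs),
        p=float(p),
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# metric-vs-age linear models


def metric_vs_age(
    values: Sequence[float],
    age_years: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
) -> TestResult:
    """OLS of a per-sample metric on age (plus optional fixed terms).

    Returns the age slope with its two-sided t-test; R^2 and the model F
    ride along in ``extra`` together with the standard error.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    x = pd.DataFrame({"age_years": np.asarray(age_years, dtype=float)})
    if covariates is not None:
        x = pd.concat([x, covariates.reset_index(drop=True)], axis=1)
    if len(y) <= x.shape[1] + 1:
        raise ValueError("too few observations for the model")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TestResult(
        name="OLS[age_years]",
        statistic=float(model.params["age_years"]),
        p=float(model.pvalues["age_years"]),
        r2=float(model.rsquared),
        df=(int(model.df_model), int(model.df_resid)),
        extra={
            "se": float(model.bse["age_years"]),
            "t": float(model.tvalues["age_years"]),
            "F": float(model.fvalue),
            "coefs": {k: float(v) for k, v in model.params.items()},
        },
    )
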