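"""Per-taxon differential abundance in the MaAsLin2 style.

Relative abundances (total-sum scaling) are log2-transformed with a
per-feature pseudo-count of half the feature's minimum nonzero relative
abundance; taxa below 10% prevalence or 0.1% maximum relative abundance are
filtered out first; each remaining taxon is fit with an independent
ordinary-least-squares model against the sample predictors, and p-values
are Benjamini-Hochberg adjusted across taxa per predictor.

Note the prevalence convention here is *any nonzero relative abundance*,
mimicking the differential-abundance tool's filter — deliberately different
from the core-microbiome definition, which requires at least 25 reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .table_io import RelAbundTable

__all__ = ["DAConfig", "da_filter", "tss_log", "fit_da", "bh_adjust"]


@dataclass
class DAConfig:
    min_prevalence: float = 0.10
    min_rel_abundance: float = 0.001
    fdr_alpha: float = 0.05
    log_base: float = 2.0

    def __post_init__(self) -> None:
        for name in ("min_prevalence", "min_rel_abundance", "fdr_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")


def da_filter(rel: RelAbundTable, cfg: DAConfig | None = None) -> list[str]:
    """Taxa passing the prevalence (nonzero share) and abundance filters."""
    cfg = cfg or DAConfig()
    df = rel.df
    prev = (df > 0).mean(axis=1)
    peak = df.max(axis=1)
    keep = (prev >= cfg.min_prevalence) & (peak >= cfg.min_rel_abundance)
    return [g for g in df.index if keep[g]]


def tss_log(rel: RelAbundTable, cfg: DAConfig | None = None) -> pd.DataFrame:
    """log2(rel + pseudo) with pseudo = half the per-feature min nonzero rel."""
    cfg = cfg or DAConfig()
    df = rel.df
    x = df.to_numpy(dtype=float)
    pseudo = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        nz = x[i][x[i] > 0]
        if nz.size == 0:
            raise ValueError(
                f"feature {df.index[i]!r} is all zero (filter before transforming)"
            )
        pseudo[i] = nz.min() / 2.0
    y = np.log(x + pseudo[:, None]) / np.log(cfg.log_base)
    return pd.DataFrame(y, index=df.index, columns=df.columns)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _encode_design(metadata: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name in predictors:
        col = metadata[name]
        if col.isna().any():
            raise ValueError(f"predictor {name!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = pd.unique(col)
            for lv in levels[1:]:
                cols[f"{name}[{lv}]"] = (col == lv).to_numpy(dtype=float)
        elif col.dtype == bool:
            cols[name] = col.to_numpy(dtype=float)
        else:
            cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=metadata.index)


def fit_da(
    transformed: pd.DataFrame,
    metadata: pd.DataFrame,
    predictors: Sequence[str],
) -> pd.DataFrame:
    """Independent OLS per taxon; BH-adjusted q per predictor.

    ``transformed`` is the taxa-x-samples log table; ``metadata`` is indexed
    by sample id.  Returns one row per (taxon, predictor term) with the
    coefficient, its standard error, two-sided t p-value and q, sorted by q.
    """
    samples = list(transformed.columns)
    design = _encode_design(metadata.loc[samples], predictors)
    x = np.column_stack([np.ones(len(samples)), design.to_numpy()])
    term_names = list(design.columns)
    n, k = x.shape
    if n <= k:
        raise ValueError("more model terms than samples")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        # identify aliased columns by testing each against the preceding ones
        aliased = []
        for j in range(1, k):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                aliased.append(term_names[j - 1])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    y = transformed.to_numpy(dtype=float).T  # samples x taxa
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # k x taxa
    resid = y - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # k x taxa
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)

    rows = []
    for j, term in enumerate(term_names, start=1):
        q = bh_adjust(pvals[j])
        for i, taxon in enumerate(transformed.index):
            rows.append(
                {
                    "taxon": taxon,
                    "predictor": term,
                    "coef": beta[j, i],
                    "se": se[j, i],
                    "p": pvals[j, i],
                    "q": q[i],
                    "n": n,
                }
            )
    out = pd.DataFrame(rows).sort_values(["q", "p"], kind="mergesort")
    return out.reset_index(drop=True)
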