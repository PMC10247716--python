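"""Genus-level community analysis: rarefaction, alpha diversity, CSS
normalization, Bray-Curtis ordination, and an LEfSe-style differential
abundance screen (Kruskal-Wallis gate + bootstrapped LDA effect size).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import FeatureTable, OrdinationResult, TableValidationError
from .stats_core import kruskal_wallis

__all__ = [
    "rarefy",
    "alpha_diversity",
    "css_normalize",
    "bray_curtis",
    "pcoa",
    "lda_effect_screen",
]


def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> FeatureTable:
    """Subsample every sample without replacement to a common depth.

    ``depth=None`` uses the minimum observed sample total (the convention
    for normalizing uneven sequencing effort across samples). Each column
    is an independent multivariate-hypergeometric draw, reproducible for a
    fixed seed.
    """
    if table.kind != "counts":
        raise TableValidationError("rarefy requires a counts table")
    totals = table.values.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        raise ValueError(f"samples below rarefaction depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty(table.values.shape, dtype=np.int64)
    counts = table.values.to_numpy().astype(np.int64)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    values = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return FeatureTable(values, table.groups, "counts")


def _chao1(c: np.ndarray) -> float:
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    # bias-corrected form avoids division by zero when no doubletons exist
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: FeatureTable, shannon_base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon (base-2 by default), Chao1, observed richness and
    Gini-Simpson (1 - sum p_i^2) indices.

    Returns a DataFrame indexed by sample id with columns
    ``shannon, chao1, observed, simpson``.
    """
    if table.kind != "counts":
        raise TableValidationError("alpha_diversity requires a counts table")
    rows = {}
    for s in table.sample_ids:
        c = table.values[s].to_numpy(dtype=float)
        total = c.sum()
        if total == 0:
            raise ValueError(f"all-zero sample: {s}")
        p = c[c > 0] / total
        shannon = float(-(p * np.log(p)).sum() / math.log(shannon_base))
        rows[s] = {
            "shannon": shannon,
            "chao1": _chao1(c),
            "observed": int((c > 0).sum()),
            "simpson": float(1.0 - (p * p).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["shannon", "chao1", "observed", "simpson"]
    ]


def css_normalize(
    table: FeatureTable, quantile: float = 0.5, scale: float = 1000.0
) -> FeatureTable:
    """Cumulative-sum scaling.

    Each sample is divided by the cumulative count of its features at or
    below its ``quantile``-th nonzero-count quantile, then multiplied by
    ``scale``. Dividing by a low-quantile cumulative sum (rather than the
    total) keeps a handful of dominant taxa from driving the scaling
    factor.
    """
    if table.kind != "counts":
        raise TableValidationError("css_normalize requires a counts table")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    out = {}
    for s in table.sample_ids:
        col = table.values[s].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"all-zero sample: {s}")
        q = np.quantile(nz, quantile)
        s_j = col[col <= q].sum()
        if s_j == 0:
            raise ValueError(f"zero CSS scaling factor for sample: {s}")
        out[s] = col / s_j * scale
    values = pd.DataFrame(out, index=table.values.index)[table.sample_ids]
    return FeatureTable(values, table.groups, "intensity")


def bray_curtis(table: FeatureTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(j,k) = sum |x_ij - x_ik| / sum (x_ij + x_ik), in [0, 1]. Not a metric
    (the triangle inequality can fail), which is why it is ordinated with
    PCoA rather than embedded directly. A pair of all-zero samples has an
    undefined ratio; it is reported as 0 with a warning.
    """
    x = table.values.to_numpy(dtype=float).T
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair; distance set to 0", RuntimeWarning)
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def pcoa(d: pd.DataFrame | np.ndarray, rtol: float = 1e-8) -> OrdinationResult:
    """Classical principal-coordinates analysis (Gower double-centering).

    Negative eigenvalues (possible for non-Euclidean dissimilarities like
    Bray-Curtis) are dropped; proportions explained are computed over the
    positive spectrum only.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        ids = [f"s{i}" for i in range(dm.shape[0])]
    n = dm.shape[0]
    if dm.shape != (n, n) or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm * dm) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * rtol
    keep = eigval > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(eigval)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=eigval,
        proportion_explained=eigval / eigval.sum() if eigval.size else eigval,
    )


def _shrunk_lda_direction(x0: np.ndarray, x1: np.ndarray, shrinkage: float = 0.5) -> np.ndarray:
    """Unit-norm discriminant direction with covariance shrunk toward its
    diagonal — required at n=6/group where the pooled covariance is singular."""
    d = x1.mean(axis=0) - x0.mean(axis=0)
    n0, n1 = x0.shape[0], x1.shape[0]
    c0 = np.cov(x0, rowvar=False, ddof=1) if n0 > 1 else np.zeros((x0.shape[1],) * 2)
    c1 = np.cov(x1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((x1.shape[1],) * 2)
    pooled = ((n0 - 1) * np.atleast_2d(c0) + (n1 - 1) * np.atleast_2d(c1)) / max(n0 + n1 - 2, 1)
    sigma = (1.0 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))
    ridge = 1e-8 * max(np.trace(sigma) / sigma.shape[0], 1e-12)
    sigma = sigma + ridge * np.eye(sigma.shape[0])
    w = np.linalg.solve(sigma, d)
    nw = np.linalg.norm(w)
    return w / nw if nw > 0 else w


def lda_effect_screen(
    table: FeatureTable,
    alpha: float = 0.05,
    lda_threshold: float = 3.0,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    shrinkage: float = 0.5,
) -> pd.DataFrame:
    """LEfSe-style differential abundance screen for a 2-group design.

    Procedure: (1) total-sum scale each sample to 1e6; (2) Kruskal-Wallis
    test per feature, keeping p < ``alpha``; (3) over ``n_boot`` seeded
    bootstrap rounds, subsample ``boot_fraction`` of each group and fit a
    shrinkage-regularized two-class LDA on the kept features, scoring each
    feature as (|w_j * (mu1_j - mu0_j)| + |mu1_j - mu0_j|) / 2 in
    per-million units; (4) lda_score = log10(1 + mean round effect).
    A feature passes iff kw_p < alpha AND lda_score > ``lda_threshold``.

    Returns a DataFrame with columns
    ``feature_id, kw_p, lda_score, enriched_group, passed``.
    """
    levels = table.group_levels
    if len(levels) != 2:
        raise ValueError(f"screen requires exactly 2 groups, got {levels}")
    g0, g1 = levels
    n0 = int((table.groups == g0).sum())
    n1 = int((table.groups == g1).sum())
    if min(n0, n1) < 3:
        raise ValueError("need at least 3 samples per group")

    totals = table.values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(f"all-zero samples: {totals.index[totals == 0].tolist()}")
    tss = (table.values / totals * 1e6).to_numpy(dtype=float)
    mask0 = (table.groups == g0).to_numpy()
    mask1 = ~mask0

    kw_p = np.ones(table.n_features)
    for i in range(table.n_features):
        kw_p[i] = kruskal_wallis([tss[i, mask0], tss[i, mask1]]).p_value
    kept = np.flatnonzero(kw_p < alpha)

    lda_score = np.zeros(table.n_features)
    if kept.size:
        # order within-group columns by sample id so the seeded bootstrap is
        # invariant to the column order of the input table
        pos0 = sorted(np.flatnonzero(mask0), key=lambda i: table.sample_ids[i])
        pos1 = sorted(np.flatnonzero(mask1), key=lambda i: table.sample_ids[i])
        x0 = tss[np.ix_(kept, pos0)].T  # samples x kept features
        x1 = tss[np.ix_(kept, pos1)].T
        k0 = max(2, math.ceil(boot_fraction * n0))
        k1 = max(2, math.ceil(boot_fraction * n1))
        rng = np.random.default_rng(seed)
        effects = np.zeros((n_boot, kept.size))
        for r in range(n_boot):
            b0 = x0[rng.choice(n0, size=k0, replace=False)]
            b1 = x1[rng.choice(n1, size=k1, replace=False)]
            w = _shrunk_lda_direction(b0, b1, shrinkage)
            d = b1.mean(axis=0) - b0.mean(axis=0)
            effects[r] = (np.abs(w * d) + np.abs(d)) / 2.0
        lda_score[kept] = np.log10(1.0 + effects.mean(axis=0))

    mean0 = tss[:, mask0].mean(axis=1)
    mean1 = tss[:, mask1].mean(axis=1)
    enriched = np.where(mean1 > mean0, g1, g0)
    passed = (kw_p < alpha) & (lda_score > lda_threshold)
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "kw_p": kw_p,
            "lda_score": lda_score,
            "enriched_group": enriched,
            "passed": passed,
        }
    )
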