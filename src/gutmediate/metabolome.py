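"""Metabolite screening: missingness filtering, feature scaling, OPLS-DA,
VIP-based differential selection, Hotelling's T2 control limit, and
hypergeometric pathway enrichment.

The OPLS-DA here is the single-y orthogonal projection to latent
structures: orthogonal components capturing class-uncorrelated variation
are stripped from X before one predictive component is extracted, so the
predictive weight vector carries all class information and VIP reduces to
sqrt(J) * |w_j| for unit-norm w.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable, TableValidationError
from .stats_core import ttest_two_sample

__all__ = [
    "missingness_filter",
    "scale_features",
    "Scaler",
    "OplsModel",
    "opls_fit",
    "vip",
    "vip_select",
    "select_differential",
    "hotelling_t2_limit",
    "pathway_enrichment",
]


def missingness_filter(
    table: FeatureTable, max_missing_frac: float = 0.6
) -> tuple[FeatureTable, int]:
    """Drop features whose zero-intensity fraction strictly exceeds
    ``max_missing_frac`` (zeros are treated as missing ion intensities).

    Returns the filtered table and the number of features dropped.
    Boundary features (fraction exactly equal to the threshold) are kept.
    """
    if table.kind == "counts":
        raise TableValidationError("missingness filter applies to intensity tables")
    frac = (table.values == 0).mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("missingness filter removed every feature", RuntimeWarning)
    out = FeatureTable(table.values.loc[keep], table.groups, table.kind)
    return out, dropped


@dataclass
class Scaler:
    """Per-feature centering/scaling state (applied column-wise over features)."""

    center: np.ndarray
    scale: np.ndarray
    method: str
    zero_variance: np.ndarray  # boolean mask of constant features

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale


def scale_features(x: np.ndarray, method: str = "unit_variance") -> tuple[np.ndarray, Scaler]:
    """Mean-center features; divide by SD (``unit_variance``), sqrt(SD)
    (``pareto``) or nothing (``none``). Constant features are centered only
    and flagged."""
    if method not in ("unit_variance", "pareto", "none"):
        raise ValueError(f"unknown scaling method {method!r}")
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to scale")
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero_var = sd == 0.0
    if method == "unit_variance":
        scale = np.where(zero_var, 1.0, sd)
    elif method == "pareto":
        scale = np.where(zero_var, 1.0, np.sqrt(sd))
    else:
        scale = np.ones_like(sd)
    scaler = Scaler(center=center, scale=scale, method=method, zero_variance=zero_var)
    return scaler.transform(x), scaler


@dataclass
class OplsModel:
    """Fitted OPLS-DA state (one predictive + ``n_ortho`` orthogonal components)."""

    weights: np.ndarray          # predictive weights w (unit norm), (J,)
    loadings: np.ndarray         # predictive loadings p, (J,)
    scores: np.ndarray           # predictive scores t, (N,)
    y_loading: float             # q
    ortho_weights: np.ndarray    # W_o, (J, A_o)
    ortho_loadings: np.ndarray   # P_o, (J, A_o)
    ortho_scores: np.ndarray     # T_o, (N, A_o)
    n_ortho: int
    scaler: Scaler
    scaling: str
    y_mean: float
    r2x: float
    r2y: float
    q2: float
    cv_folds: int
    seed: int
    feature_ids: list[str] | None = None
    fitted: bool = field(default=True)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        """Predict the class response for new samples (raw feature space)."""
        xs = self.scaler.transform(np.atleast_2d(np.asarray(x_new, dtype=float)))
        for a in range(self.n_ortho):
            t_o = xs @ self.ortho_weights[:, a]
            xs = xs - np.outer(t_o, self.ortho_loadings[:, a])
        return xs @ self.weights * self.y_loading + self.y_mean


def _opls_core(xs: np.ndarray, yc: np.ndarray, n_ortho: int):
    """O-PLS decomposition of scaled X against centered y (Trygg-Wold)."""
    xd = xs.copy()
    w_o, p_o, t_o = [], [], []
    for _ in range(n_ortho):
        w = xd.T @ yc
        w /= np.linalg.norm(w)
        t = xd @ w
        p = xd.T @ t / (t @ t)
        wo = p - (w @ p) * w
        n_wo = np.linalg.norm(wo)
        if n_wo < 1e-12:  # no orthogonal variation left
            break
        wo /= n_wo
        to = xd @ wo
        po = xd.T @ to / (to @ to)
        xd = xd - np.outer(to, po)
        w_o.append(wo)
        p_o.append(po)
        t_o.append(to)
    w = xd.T @ yc
    w /= np.linalg.norm(w)
    t = xd @ w
    p = xd.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    wo_m = np.column_stack(w_o) if w_o else np.zeros((xs.shape[1], 0))
    po_m = np.column_stack(p_o) if p_o else np.zeros((xs.shape[1], 0))
    to_m = np.column_stack(t_o) if t_o else np.zeros((xs.shape[0], 0))
    return w, p, t, q, wo_m, po_m, to_m


def _cv_folds_assignment(n: int, cv_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled partition into ``cv_folds`` near-equal held-out sets; falls
    back to leave-one-out when there are fewer samples than folds."""
    if n < cv_folds:
        warnings.warn(
            f"{n} samples < {cv_folds} folds; using leave-one-out", RuntimeWarning
        )
        return [np.array([i]) for i in range(n)]
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, cv_folds)]


def opls_fit(
    x,
    y,
    n_ortho: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
    scaling: str = "unit_variance",
    feature_ids: list[str] | None = None,
) -> OplsModel:
    """Fit OPLS-DA of a +/-1 class encoding on a samples x features matrix.

    R2Y is the training-data fraction of class variance explained; Q2 is
    its cross-validated analogue, 1 - PRESS/SS over seeded folds (each
    fold refits scaling and the full decomposition on the training part).
    Q2 <= 0 on permuted labels is the standard overfitting guard.
    """
    if isinstance(x, pd.DataFrame):
        if feature_ids is None:
            feature_ids = list(x.columns)
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, j = x.shape
    if yv.size != n:
        raise ValueError("y length must match the number of samples (rows of X)")
    if np.var(yv) == 0:
        raise ValueError("y has zero variance")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} >= rank(X)={rank}")

    xs, scaler = scale_features(x, scaling)
    y_mean = yv.mean()
    yc = yv - y_mean
    w, p, t, q, wo, po, to = _opls_core(xs, yc, n_ortho)

    ss_y = float(yc @ yc)
    resid = yc - q * t
    r2y = 1.0 - float(resid @ resid) / ss_y
    ss_x = float((xs * xs).sum())
    modeled = float(np.outer(t, p).ravel() @ np.outer(t, p).ravel())
    for a in range(to.shape[1]):
        comp = np.outer(to[:, a], po[:, a])
        modeled += float((comp * comp).sum())
    r2x = modeled / ss_x if ss_x > 0 else 0.0

    rng = np.random.default_rng(seed)
    press = 0.0
    ss_tot = 0.0
    for held in _cv_folds_assignment(n, cv_folds, rng):
        train = np.setdiff1d(np.arange(n), held)
        xs_tr, sc_tr = scale_features(x[train], scaling)
        y_tr = yv[train]
        yc_tr = y_tr - y_tr.mean()
        if np.all(yc_tr == 0):
            continue
        w_t, p_t, t_t, q_t, wo_t, po_t, _ = _opls_core(xs_tr, yc_tr, n_ortho)
        x_te = sc_tr.transform(x[held])
        for a in range(wo_t.shape[1]):
            t_o = x_te @ wo_t[:, a]
            x_te = x_te - np.outer(t_o, po_t[:, a])
        y_hat = x_te @ w_t * q_t + y_tr.mean()
        press += float(((yv[held] - y_hat) ** 2).sum())
        ss_tot += float(((yv[held] - y_tr.mean()) ** 2).sum())
    q2 = 1.0 - press / ss_tot if ss_tot > 0 else float("nan")

    return OplsModel(
        weights=w, loadings=p, scores=t, y_loading=float(q),
        ortho_weights=wo, ortho_loadings=po, ortho_scores=to,
        n_ortho=to.shape[1], scaler=scaler, scaling=scaling, y_mean=float(y_mean),
        r2x=float(r2x), r2y=float(r2y), q2=float(q2),
        cv_folds=cv_folds, seed=seed, feature_ids=feature_ids,
    )


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in the projection over predictive component(s).

    With one predictive component and unit-norm weights this is
    VIP_j = sqrt(J) * |w_j|, so sum(VIP^2) = J exactly — asserted in tests
    as a numerical identity.
    """
    if not getattr(model, "fitted", False):
        raise ValueError("model is not fitted")
    j = model.n_features
    w2 = model.weights**2
    return np.sqrt(j * w2 / w2.sum())


def vip_select(
    table: FeatureTable,
    model: OplsModel,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    positive: str = "hypoxia",
    transform: str = "log10",
    t_variant: str = "student",
) -> pd.DataFrame:
    """Per-metabolite VIP + two-tailed t-test selection table.

    The t-test runs on ``log10(x + 1)``-transformed intensities by default
    (``transform="raw"`` uses raw peak areas); direction (up/down in the
    ``positive`` group) is always computed on raw group means, ties
    reported as "up". Selection uses strict thresholds:
    VIP > ``vip_threshold`` AND p < ``alpha``.
    """
    levels = table.group_levels
    if len(levels) != 2:
        raise ValueError("selection requires exactly 2 groups")
    other = [g for g in levels if g != positive][0]
    vips = vip(model)
    if len(vips) != table.n_features:
        raise ValueError("model feature count does not match table")
    raw_pos = table.group_columns(positive).to_numpy(dtype=float)
    raw_other = table.group_columns(other).to_numpy(dtype=float)
    if transform == "log10":
        x_pos, x_other = np.log10(raw_pos + 1.0), np.log10(raw_other + 1.0)
    elif transform == "raw":
        x_pos, x_other = raw_pos, raw_other
    else:
        raise ValueError(f"unknown transform {transform!r}")
    t_p = np.array(
        [ttest_two_sample(x_pos[i], x_other[i], t_variant).p_value for i in range(len(vips))]
    )
    direction = np.where(raw_pos.mean(axis=1) >= raw_other.mean(axis=1), "up", "down")
    selected = (vips > vip_threshold) & (t_p < alpha)
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "vip": vips,
            "t_p": t_p,
            "direction": direction,
            "selected": selected,
        }
    )


def select_differential(
    vip_table: pd.DataFrame,
    vip_threshold: float | None = None,
    alpha: float | None = None,
) -> set[str]:
    """Ids passing the strict VIP > threshold & p < alpha gate.

    Boundary values (VIP exactly at the threshold, p exactly at alpha) are
    excluded. With no thresholds given, the ``selected`` flags computed by
    :func:`vip_select` are used as-is.
    """
    if vip_threshold is None and alpha is None:
        return set(vip_table.loc[vip_table["selected"], "feature_id"])
    vt = 1.0 if vip_threshold is None else vip_threshold
    al = 0.05 if alpha is None else alpha
    mask = (vip_table["vip"] > vt) & (vip_table["t_p"] < al)
    return set(vip_table.loc[mask, "feature_id"])


def hotelling_t2_limit(model: OplsModel, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """F-distribution control limit for Hotelling's T2 on the model scores,
    plus each sample's T2.

    T2_crit = A (N^2 - 1) / (N (N - A)) * F_{1-alpha}(A, N-A) where A counts
    all score columns (predictive + orthogonal). The (1-alpha) ellipse in
    score plots flags multivariate outliers.
    """
    scores = np.column_stack([model.scores[:, None], model.ortho_scores])
    n, a = scores.shape
    if n <= a:
        raise ValueError(f"need more samples ({n}) than score columns ({a})")
    var = scores.var(axis=0, ddof=1)
    t2 = ((scores**2) / var).sum(axis=1)
    f_crit = stats.f.ppf(1.0 - alpha, a, n - a)
    limit = a * (n**2 - 1) / (n * (n - a)) * f_crit
    return float(limit), t2


def pathway_enrichment(
    selected, annotation: dict, background
) -> pd.DataFrame:
    """Hypergeometric over-representation of each annotated pathway in the
    selected metabolite set, sorted by p-value.

    ``annotation`` maps pathway id -> iterable of member metabolite ids
    (all members must belong to ``background``).
    """
    from .stats_core import hypergeometric_enrichment

    rows = []
    for pathway_id in sorted(annotation):
        members = set(annotation[pathway_id])
        res = hypergeometric_enrichment(selected, members, background)
        rows.append(
            {
                "pathway": pathway_id,
                "overlap": int(res.statistic),
                "pathway_size": len(members),
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size", "p_value"])
    return df.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)
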