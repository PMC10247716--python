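"""Causal mediation analysis for (exposure, mediator, outcome) triads.

For each triad the three classical regressions are fitted by OLS with the
binary treatment (hypoxia/normoxia) as an adjustment covariate:

    total effect model    Y = b0 + b1*X        + g1*Z + e1
    mediator model        M = b0 + b2*X        + g2*Z + e2
    outcome model         Y = b0 + b3*M + b4*X + g3*Z + e3

The average causal mediation effect is the product of coefficients
ACME = b2*b3, the average direct effect ADE = b4, and the total effect b1;
for OLS fits on identical samples and covariates the decomposition
ACME + ADE = total holds exactly. Uncertainty comes from quasi-Bayesian
Monte Carlo: coefficients are drawn from their asymptotic Gaussian
sampling distributions (independently across the two models, jointly
within the outcome model) and the ACME/ADE/total draw distributions give
percentile intervals and sign-based p-values.

A Baron-Kenny-style assumption gate (significant b1, b2, b3, and
|b4| < |b1|) screens triads before effect estimation; both causal
directions (genus -> metabolite -> hormone and the reverse) are screened
symmetrically.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable

__all__ = [
    "MediationTriad",
    "TriadFit",
    "MediationResult",
    "CollinearityError",
    "fit_triad",
    "assumption_gate",
    "estimate_effects",
    "screen_triples",
    "results_to_frame",
    "edge_list",
    "DIRECTION_H2G",
    "DIRECTION_G2H",
]

DIRECTION_H2G = "hormone->metabolite->genus"
DIRECTION_G2H = "genus->metabolite->hormone"


class CollinearityError(ValueError):
    """Raised when a triad's design matrix is rank-deficient."""


@dataclass(frozen=True)
class MediationTriad:
    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    z: np.ndarray
    x_id: str = "X"
    m_id: str = "M"
    y_id: str = "Y"
    direction: str = DIRECTION_G2H

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.m) == len(self.y) == len(self.z) == n):
            raise ValueError("triad vectors must share length")
        if n < 6:
            raise ValueError("need at least 6 observations per triad")
        zu = set(np.unique(self.z))
        if not zu <= {0.0, 1.0}:
            raise ValueError("z must be a 0/1 treatment indicator")


@dataclass
class OlsBlock:
    """One fitted OLS model: coefficients, covariance, SEs, p-values."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sigma2: float
    df_resid: int

    def __getitem__(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def p_of(self, name: str) -> float:
        return float(self.p[self.names.index(name)])


def _ols(design: np.ndarray, y: np.ndarray, names: list[str]) -> OlsBlock:
    n, k = design.shape
    if np.linalg.matrix_rank(design) < k:
        raise CollinearityError(f"rank-deficient design ({names})")
    if n < k + 2:
        raise ValueError(f"too few observations (n={n}) for {k} coefficients")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tvals), df)
    return OlsBlock(names=names, beta=beta, cov=cov, se=se, p=p, sigma2=sigma2, df_resid=df)


@dataclass
class TriadFit:
    triad: MediationTriad
    total_model: OlsBlock    # Y ~ 1 + X + Z
    mediator_model: OlsBlock  # M ~ 1 + X + Z
    outcome_model: OlsBlock  # Y ~ 1 + M + X + Z

    @property
    def beta1(self) -> float:
        return self.total_model["x"]

    @property
    def beta2(self) -> float:
        return self.mediator_model["x"]

    @property
    def beta3(self) -> float:
        return self.outcome_model["m"]

    @property
    def beta4(self) -> float:
        return self.outcome_model["x"]


def fit_triad(triad: MediationTriad) -> TriadFit:
    """Fit the three adjustment-covariate OLS regressions of a triad.

    Raises :class:`CollinearityError` when X is collinear with the
    treatment indicator (e.g. constant within groups), in which case the
    triad should be skipped with a reason.
    """
    x, m, y, z = (np.asarray(v, dtype=float) for v in (triad.x, triad.m, triad.y, triad.z))
    ones = np.ones_like(x)
    d_xz = np.column_stack([ones, x, z])
    d_mxz = np.column_stack([ones, m, x, z])
    return TriadFit(
        triad=triad,
        total_model=_ols(d_xz, y, ["intercept", "x", "z"]),
        mediator_model=_ols(d_xz, m, ["intercept", "x", "z"]),
        outcome_model=_ols(d_mxz, y, ["intercept", "m", "x", "z"]),
    )


def assumption_gate(fit: TriadFit, alpha: float = 0.05) -> dict:
    """Four Baron-Kenny-style screening conditions.

    (1) X predicts Y (p(b1) < alpha); (2) X predicts M (p(b2) < alpha);
    (3) M predicts Y adjusting for X (p(b3) < alpha); (4) the X->Y
    relationship weakens when M is controlled (strict |b4| < |b1|).
    """
    flags = {
        "x_predicts_y": fit.total_model.p_of("x") < alpha,
        "x_predicts_m": fit.mediator_model.p_of("x") < alpha,
        "m_predicts_y": fit.outcome_model.p_of("m") < alpha,
        "weakened": abs(fit.beta4) < abs(fit.beta1),
    }
    flags["all"] = all(flags.values())
    return flags


@dataclass
class MediationResult:
    x_id: str
    m_id: str
    y_id: str
    direction: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    acme_p: float
    ade_p: float
    total_p: float
    n_sims: int
    seed: int
    gate: dict = field(default_factory=dict)


def _mc_pvalue(draws: np.ndarray, n_sims: int) -> float:
    p = 2.0 * min((draws <= 0).mean(), (draws >= 0).mean())
    return float(np.clip(p, 2.0 / n_sims, 1.0))


def estimate_effects(
    fit: TriadFit, n_sims: int = 1000, seed: int = 0, gate: dict | None = None
) -> MediationResult:
    """Quasi-Bayesian Monte Carlo ACME/ADE/total estimation.

    Point estimates come straight from the OLS coefficients
    (acme = b2*b3, ade = b4, total = b1; acme + ade == total to numerical
    precision). Draws come from each model's finite-sample coefficient
    distribution — a multivariate t with the residual degrees of freedom
    (the exact posterior under the standard noninformative OLS prior),
    which stays calibrated at the n=12 sample sizes typical here where
    plain Gaussian draws are anti-conservative. b2 is drawn from the
    mediator model, (b3, b4) jointly from the outcome model, independent
    across models. 95% intervals are the 2.5/97.5 percentiles of the draw
    distributions; p-values are two-sided sign fractions floored at
    2/n_sims.
    """
    if n_sims < 100:
        raise ValueError("n_sims < 100 yields unstable percentiles")
    rng = np.random.default_rng(seed)
    mm = fit.mediator_model
    b2 = fit.beta2 + mm.se_of("x") * rng.standard_t(mm.df_resid, size=n_sims)
    om = fit.outcome_model
    idx = [om.names.index("m"), om.names.index("x")]
    mean34 = om.beta[idx]
    cov34 = om.cov[np.ix_(idx, idx)]
    chol = np.linalg.cholesky(cov34)
    gauss = rng.standard_normal(size=(n_sims, 2)) @ chol.T
    scale = np.sqrt(om.df_resid / rng.chisquare(om.df_resid, size=n_sims))
    b34 = mean34 + gauss * scale[:, None]
    acme_d = b2 * b34[:, 0]
    ade_d = b34[:, 1]
    total_d = acme_d + ade_d

    acme, ade, total = fit.beta2 * fit.beta3, fit.beta4, fit.beta1
    prop = acme / total if abs(total) > 1e-12 else float("nan")
    ci = lambda d: tuple(np.percentile(d, [2.5, 97.5]))
    return MediationResult(
        x_id=fit.triad.x_id, m_id=fit.triad.m_id, y_id=fit.triad.y_id,
        direction=fit.triad.direction,
        acme=acme, ade=ade, total=total, prop_mediated=prop,
        acme_ci=ci(acme_d), ade_ci=ci(ade_d), total_ci=ci(total_d),
        acme_p=_mc_pvalue(acme_d, n_sims),
        ade_p=_mc_pvalue(ade_d, n_sims),
        total_p=_mc_pvalue(total_d, n_sims),
        n_sims=n_sims, seed=seed, gate=dict(gate or {}),
    )


def triad_seed(master_seed: int, direction: str, x_id: str, m_id: str, y_id: str) -> int:
    """Deterministic, order-independent per-triad seed (< 2^31)."""
    label = f"{direction}|{x_id}|{m_id}|{y_id}"
    return (int(master_seed) + zlib.crc32(label.encode())) % (2**31)


def transform_genus(counts: FeatureTable, pseudo: float = 1e-6) -> pd.DataFrame:
    """log10(relative abundance + pseudo): variance-stabilizing transform
    for compositional genus counts entering the regressions."""
    if counts.kind == "counts":
        rel = counts.relative_abundance().values
    else:
        rel = counts.values
    return np.log10(rel + pseudo)


def transform_metabolite(table: FeatureTable) -> pd.DataFrame:
    """log10(intensity + 1) for skewed peak-area mediators."""
    return np.log10(table.values + 1.0)


def screen_triples(
    hormones: FeatureTable,
    genera: FeatureTable,
    metabolites: FeatureTable,
    candidates: dict,
    direction: str = "both",
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
    require_gate: bool = True,
    treatment: str = "hypoxia",
) -> tuple[list[MediationResult], list[dict]]:
    """Exhaustive bidirectional mediation screen over candidate features.

    ``candidates`` maps ``{"hormones": ids, "genera": ids, "metabolites":
    ids}`` — normally the differential hormones, LDA-passed genera and
    VIP-selected metabolites from the upstream screens. Every (X, M, Y)
    combination in each requested direction is fitted; by default only
    triads passing the four-assumption gate receive effect estimates.
    Results are deterministically ordered and per-triad seeds derive from
    the master seed plus a stable label hash, so the output is independent
    of enumeration order.

    Returns (results, skipped) where ``skipped`` records collinear or
    gate-failed triads with reasons.
    """
    directions = [DIRECTION_H2G, DIRECTION_G2H] if direction == "both" else [direction]
    for d in directions:
        if d not in (DIRECTION_H2G, DIRECTION_G2H):
            raise ValueError(f"unknown direction {d!r}")
    h_ids = sorted(set(candidates.get("hormones", [])))
    g_ids = sorted(set(candidates.get("genera", [])))
    m_ids = sorted(set(candidates.get("metabolites", [])))

    z = hormones.group_indicator(treatment)
    h_mat = hormones.values
    g_mat = transform_genus(genera)
    m_mat = transform_metabolite(metabolites)
    if list(g_mat.columns) != list(h_mat.columns) or list(m_mat.columns) != list(h_mat.columns):
        raise ValueError("tables must share identical sample ordering")

    results: list[MediationResult] = []
    skipped: list[dict] = []
    for d in directions:
        if d == DIRECTION_H2G:
            combos = itertools.product(h_ids, m_ids, g_ids)
            x_src, y_src = h_mat, g_mat
        else:
            combos = itertools.product(g_ids, m_ids, h_ids)
            x_src, y_src = g_mat, h_mat
        for x_id, m_id, y_id in combos:
            triad = MediationTriad(
                x=x_src.loc[x_id].to_numpy(dtype=float),
                m=m_mat.loc[m_id].to_numpy(dtype=float),
                y=y_src.loc[y_id].to_numpy(dtype=float),
                z=z, x_id=x_id, m_id=m_id, y_id=y_id, direction=d,
            )
            try:
                fit = fit_triad(triad)
            except (CollinearityError, ValueError) as exc:
                skipped.append(
                    {"direction": d, "x_id": x_id, "m_id": m_id, "y_id": y_id,
                     "reason": f"fit_error: {exc}"}
                )
                continue
            gate = assumption_gate(fit, alpha)
            if require_gate and not gate["all"]:
                skipped.append(
                    {"direction": d, "x_id": x_id, "m_id": m_id, "y_id": y_id,
                     "reason": "assumption_gate", "gate": gate}
                )
                continue
            s = triad_seed(seed, d, x_id, m_id, y_id)
            results.append(estimate_effects(fit, n_sims=n_sims, seed=s, gate=gate))
    results.sort(key=lambda r: (r.direction, r.x_id, r.m_id, r.y_id))
    return results, skipped


def significant_results(results: list[MediationResult], alpha: float = 0.05):
    """Triads whose ACME is significant at ``alpha``."""
    return [r for r in results if r.acme_p < alpha]


def results_to_frame(results: list[MediationResult]) -> pd.DataFrame:
    cols = [
        "direction", "x_id", "m_id", "y_id", "acme", "ade", "total",
        "prop_mediated", "acme_ci_lo", "acme_ci_hi", "ade_ci_lo", "ade_ci_hi",
        "total_ci_lo", "total_ci_hi", "acme_p", "ade_p", "total_p",
        "gate_pass", "n_sims", "seed",
    ]
    rows = [
        {
            "direction": r.direction, "x_id": r.x_id, "m_id": r.m_id, "y_id": r.y_id,
            "acme": r.acme, "ade": r.ade, "total": r.total,
            "prop_mediated": r.prop_mediated,
            "acme_ci_lo": r.acme_ci[0], "acme_ci_hi": r.acme_ci[1],
            "ade_ci_lo": r.ade_ci[0], "ade_ci_hi": r.ade_ci[1],
            "total_ci_lo": r.total_ci[0], "total_ci_hi": r.total_ci[1],
            "acme_p": r.acme_p, "ade_p": r.ade_p, "total_p": r.total_p,
            "gate_pass": bool(r.gate.get("all", False)),
            "n_sims": r.n_sims, "seed": r.seed,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=cols)


def edge_list(results: list[MediationResult], alpha: float = 0.05) -> list[dict]:
    """JSON-ready mediation network edges (X -> M -> Y), one entry per
    significant triad; ``sign`` carries the ACME coefficient sign for
    positive/negative edge coloring."""
    edges = []
    for r in significant_results(results, alpha):
        edges.append(
            {
                "x": r.x_id, "m": r.m_id, "y": r.y_id,
                "direction": r.direction,
                "acme": r.acme, "acme_p": r.acme_p,
                "sign": "positive" if r.acme >= 0 else "negative",
            }
        )
    return edges
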