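"""Synthetic two-group multi-omics studies with recorded ground truth.

Emulates the statistical shape of a hypobaric-hypoxia rat study: a 2 x 6
design (control/hypoxia), a compositional genus count table, zero-inflated
log-normal fecal and serum metabolite intensity matrices, a 9-hormone
panel, planted group effects in each table, and planted
X -> M -> Y mediation triads with known path coefficients. Every random
choice derives from per-table child streams of a single master seed, so a
config generates bit-identical studies.

Planted triads are defined on standardized latent variables
(X* = shift*Zc + N(0,1), M* = a X* + eps, Y* = b M* + c' X* + delta Zc +
eps') and mapped affinely onto each table's native scale (hormone units,
log10 peak area, log10 relative abundance), so ``a`` and ``b`` are
interpretable as path coefficients on the unit-noise latent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .mediation import DIRECTION_G2H, DIRECTION_H2G

__all__ = [
    "PlantedTriad",
    "SyntheticConfig",
    "StudyTruth",
    "SyntheticStudy",
    "generate_study",
    "truth_confusion",
    "triad_confusion",
    "paper_scale_config",
    "DEFAULT_HORMONES",
]

DEFAULT_HORMONES = ["CRH", "ACTH", "CORT", "TRH", "tT4", "TSH", "fT4", "tT3", "fT3"]

# latent -> table-scale affine maps
_MET_LOC, _MET_SCALE = 5.5, 0.35        # log10 peak area
_GENUS_LOC, _GENUS_SCALE = np.log10(0.02), 0.15  # log10 relative abundance


@dataclass
class PlantedTriad:
    """A ground-truth mediation chain to plant into the study tables."""

    direction: str = DIRECTION_G2H
    a: float = 1.2          # X -> M path (latent scale)
    b: float = 1.2          # M -> Y path
    c_prime: float = 0.0    # direct X -> Y path
    x_shift: float = 2.0    # group shift on X (SD units) making it a screen candidate
    z_effect: float = 0.0   # direct treatment effect on Y
    noise_sd_m: float = 1.0
    noise_sd_y: float = 1.0
    m_table: str = "fecal"  # which metabolite matrix hosts the mediator
    x_id: str | None = None  # auto-assigned when None
    m_id: str | None = None
    y_id: str | None = None


@dataclass
class SyntheticConfig:
    """Study-generator settings (defaults are desk-scale; see
    :func:`paper_scale_config` for full-size tables)."""

    n_per_group: int = 6
    n_genera: int = 60
    n_fecal_mets: int = 300
    n_serum_mets: int = 150
    n_hormones: int = 9
    library_size_mean: float = 30000.0
    library_size_disp: float = 0.2      # lognormal sigma of library sizes
    dirichlet_concentration: float = 300.0
    zero_inflation_rate: float = 0.15   # mean per-feature zero probability
    n_diff_genera: int = 8
    genus_log2_fc: float = 2.0
    n_diff_fecal: int = 20
    n_diff_serum: int = 12
    met_log2_fc: float = 2.0
    n_diff_hormones: int = 5
    hormone_effect_sd: float = 3.0      # group shift in within-group SD units
    planted_triads: list[PlantedTriad] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_genera", "n_fecal_mets", "n_serum_mets", "n_hormones"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_diff_genera > self.n_genera:
            raise ValueError("n_diff_genera exceeds n_genera")
        if self.n_diff_fecal > self.n_fecal_mets or self.n_diff_serum > self.n_serum_mets:
            raise ValueError("differential metabolite count exceeds table size")
        if self.n_diff_hormones > self.n_hormones:
            raise ValueError("n_diff_hormones exceeds n_hormones")
        if not 0.0 <= self.zero_inflation_rate < 1.0:
            raise ValueError("zero_inflation_rate must be in [0, 1)")


def paper_scale_config(**overrides) -> SyntheticConfig:
    """Full-size preset: 254 genera, 2945 fecal and 1457 serum metabolites."""
    base = dict(n_genera=254, n_fecal_mets=2945, n_serum_mets=1457,
                n_diff_genera=13, n_diff_fecal=233, n_diff_serum=66)
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class StudyTruth:
    diff_hormones: set
    diff_genera: set
    diff_fecal: set
    diff_serum: set
    triads: list[dict]
    library_sizes: pd.Series


@dataclass
class SyntheticStudy:
    hormones: FeatureTable
    genus: FeatureTable
    fecal: FeatureTable
    serum: FeatureTable
    groups: pd.Series
    truth: StudyTruth
    config: SyntheticConfig

    def metabolites_combined(self) -> FeatureTable:
        """Fecal + serum matrices row-concatenated with table-tagged ids."""
        f = self.fecal.values.copy()
        f.index = [f"fecal:{i}" for i in f.index]
        s = self.serum.values.copy()
        s.index = [f"serum:{i}" for i in s.index]
        return FeatureTable(pd.concat([f, s]), self.groups, "intensity")


def _alternating_signs(k: int) -> np.ndarray:
    return np.where(np.arange(k) % 2 == 0, 1.0, -1.0)


def _zero_mask(rng, shape, mean_rate):
    """Per-feature zero probabilities ~ Beta(1, (1-r)/r): mean r with a
    heavy right tail so that some features exceed the 60% missingness cut."""
    if mean_rate == 0:
        return np.zeros(shape, dtype=bool)
    rates = rng.beta(1.0, (1.0 - mean_rate) / mean_rate, size=shape[0])
    return rng.random(shape) < rates[:, None]


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a complete study (4 tables + metadata + ground truth)."""
    n = 2 * config.n_per_group
    samples = [f"C{i + 1:02d}" for i in range(config.n_per_group)] + [
        f"H{i + 1:02d}" for i in range(config.n_per_group)
    ]
    groups = pd.Series(
        ["control"] * config.n_per_group + ["hypoxia"] * config.n_per_group,
        index=samples, name="group",
    )
    z = (groups == "hypoxia").to_numpy(dtype=float)
    zc = z - 0.5

    ss = np.random.SeedSequence(config.seed)
    rng_h, rng_g, rng_f, rng_s, rng_t = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    # --- hormones -------------------------------------------------------
    if config.n_hormones <= len(DEFAULT_HORMONES):
        h_ids = DEFAULT_HORMONES[: config.n_hormones]
    else:
        h_ids = DEFAULT_HORMONES + [
            f"Hormone_{i + 1:02d}" for i in range(config.n_hormones - len(DEFAULT_HORMONES))
        ]
    h_mean = rng_h.uniform(10.0, 100.0, config.n_hormones)
    h_sd = 0.1 * h_mean
    h_vals = h_mean[:, None] + h_sd[:, None] * rng_h.normal(size=(config.n_hormones, n))
    # HPA-axis style pattern: first three shifted up, the next two down, then alternate
    h_signs = np.array([1, 1, 1, -1, -1] + list(_alternating_signs(max(config.n_hormones - 5, 0))))
    diff_h_idx = list(range(config.n_diff_hormones))
    for i in diff_h_idx:
        h_vals[i] += h_signs[i] * config.hormone_effect_sd * h_sd[i] * z
    diff_hormones = {h_ids[i] for i in diff_h_idx}

    # --- genus composition ---------------------------------------------
    g_ids = [f"Genus_{i + 1:03d}" for i in range(config.n_genera)]
    base_logw = rng_g.normal(0.0, 1.5, config.n_genera)
    base = np.exp(base_logw)
    base /= base.sum()
    perm = rng_g.permutation(config.n_genera)
    diff_g_idx = list(perm[: config.n_diff_genera])
    g_signs = _alternating_signs(config.n_diff_genera)
    props_hyp = base.copy()
    for sign, i in zip(g_signs, diff_g_idx):
        props_hyp[i] *= 2.0 ** (sign * config.genus_log2_fc)
    props_hyp /= props_hyp.sum()
    diff_genera = {g_ids[i] for i in diff_g_idx}

    # --- metabolite matrices -------------------------------------------
    def _metabolites(rng, prefix, n_feat, n_diff):
        ids = [f"{prefix}_{i + 1:04d}" for i in range(n_feat)]
        mu = rng.uniform(4.0, 7.0, n_feat)
        sigma = rng.uniform(0.15, 0.4, n_feat)
        logx = mu[:, None] + sigma[:, None] * rng.normal(size=(n_feat, n))
        idx = list(rng.permutation(n_feat)[:n_diff])
        signs = _alternating_signs(n_diff)
        for sign, i in zip(signs, idx):
            logx[i] += sign * config.met_log2_fc * np.log10(2.0) * z
        return ids, 10.0**logx, {ids[i] for i in idx}

    f_ids, f_vals, diff_fecal = _metabolites(rng_f, "FecalMet", config.n_fecal_mets, config.n_diff_fecal)
    s_ids, s_vals, diff_serum = _metabolites(rng_s, "SerumMet", config.n_serum_mets, config.n_diff_serum)

    # --- planted mediation triads --------------------------------------
    h_pool = [i for i, hid in enumerate(h_ids) if hid not in diff_hormones]
    g_pool = [i for i, gid in enumerate(g_ids) if gid not in diff_genera]
    f_pool = [i for i, fid in enumerate(f_ids) if fid not in diff_fecal]
    s_pool = [i for i, sid in enumerate(s_ids) if sid not in diff_serum]
    planted_genus_props: dict[int, np.ndarray] = {}
    mask_exempt_fecal: set[int] = set()
    mask_exempt_serum: set[int] = set()
    truth_triads: list[dict] = []

    def _claim(pool, ids, requested, what):
        if requested is None:
            if not pool:
                raise ValueError(f"no spare {what} features to host a planted triad")
            return pool.pop(0)
        i = ids.index(requested)
        if i not in pool:
            raise ValueError(
                f"planted {what} feature {requested!r} conflicts with a differential set"
            )
        pool.remove(i)
        return i

    for triad in config.planted_triads:
        if triad.direction not in (DIRECTION_H2G, DIRECTION_G2H):
            raise ValueError(f"unknown triad direction {triad.direction!r}")
        if triad.m_table not in ("fecal", "serum"):
            raise ValueError(f"unknown mediator table {triad.m_table!r}")
        x_std = triad.x_shift * zc + rng_t.normal(size=n)
        m_std = triad.a * x_std + rng_t.normal(0.0, triad.noise_sd_m, size=n)
        y_std = (
            triad.b * m_std + triad.c_prime * x_std + triad.z_effect * zc
            + rng_t.normal(0.0, triad.noise_sd_y, size=n)
        )
        m_pool, m_ids_all, m_vals, diff_m = (
            (f_pool, f_ids, f_vals, diff_fecal) if triad.m_table == "fecal"
            else (s_pool, s_ids, s_vals, diff_serum)
        )
        mi = _claim(m_pool, m_ids_all, triad.m_id, f"{triad.m_table} metabolite")
        m_vals[mi] = 10.0 ** (_MET_LOC + _MET_SCALE * m_std)
        diff_m.add(m_ids_all[mi])
        (mask_exempt_fecal if triad.m_table == "fecal" else mask_exempt_serum).add(mi)

        if triad.direction == DIRECTION_H2G:
            xi = _claim(h_pool, h_ids, triad.x_id, "hormone")
            yi = _claim(g_pool, g_ids, triad.y_id, "genus")
            h_vals[xi] = h_mean[xi] + h_sd[xi] * x_std
            planted_genus_props[yi] = 10.0 ** (_GENUS_LOC + _GENUS_SCALE * y_std)
            diff_hormones.add(h_ids[xi])
            diff_genera.add(g_ids[yi])
            x_name, y_name = h_ids[xi], g_ids[yi]
        else:
            xi = _claim(g_pool, g_ids, triad.x_id, "genus")
            yi = _claim(h_pool, h_ids, triad.y_id, "hormone")
            planted_genus_props[xi] = 10.0 ** (_GENUS_LOC + _GENUS_SCALE * x_std)
            h_vals[yi] = h_mean[yi] + h_sd[yi] * y_std
            diff_genera.add(g_ids[xi])
            diff_hormones.add(h_ids[yi])
            x_name, y_name = g_ids[xi], h_ids[yi]
        truth_triads.append(
            {
                "direction": triad.direction, "x_id": x_name,
                "m_id": f"{triad.m_table}:{m_ids_all[mi]}", "y_id": y_name,
                "m_table": triad.m_table, "a": triad.a, "b": triad.b,
                "c_prime": triad.c_prime, "x_shift": triad.x_shift,
                "z_effect": triad.z_effect,
            }
        )

    # --- draw genus counts ---------------------------------------------
    lib = np.round(
        rng_g.lognormal(np.log(config.library_size_mean), config.library_size_disp, n)
    ).astype(np.int64)
    counts = np.zeros((config.n_genera, n), dtype=np.int64)
    planted_idx = sorted(planted_genus_props)
    free_idx = [i for i in range(config.n_genera) if i not in planted_genus_props]
    for j in range(n):
        p_group = props_hyp if z[j] == 1.0 else base
        props_j = rng_g.dirichlet(config.dirichlet_concentration * p_group)
        if planted_idx:
            planted_vals = np.array([planted_genus_props[i][j] for i in planted_idx])
            free_total = props_j[free_idx].sum()
            remain = max(1.0 - planted_vals.sum(), 1e-9)
            props_j[free_idx] *= remain / free_total
            props_j[planted_idx] = planted_vals
            props_j = props_j / props_j.sum()
        counts[:, j] = rng_g.multinomial(lib[j], props_j)

    # --- zero-inflate metabolite intensities ---------------------------
    f_mask = _zero_mask(rng_f, f_vals.shape, config.zero_inflation_rate)
    f_mask[sorted(mask_exempt_fecal), :] = False
    f_vals = np.where(f_mask, 0.0, f_vals)
    s_mask = _zero_mask(rng_s, s_vals.shape, config.zero_inflation_rate)
    s_mask[sorted(mask_exempt_serum), :] = False
    s_vals = np.where(s_mask, 0.0, s_vals)

    truth = StudyTruth(
        diff_hormones=diff_hormones, diff_genera=diff_genera,
        diff_fecal=diff_fecal, diff_serum=diff_serum,
        triads=truth_triads,
        library_sizes=pd.Series(lib, index=samples, name="library_size"),
    )
    return SyntheticStudy(
        hormones=FeatureTable(pd.DataFrame(h_vals, index=h_ids, columns=samples), groups, "hormone"),
        genus=FeatureTable(pd.DataFrame(counts, index=g_ids, columns=samples), groups, "counts"),
        fecal=FeatureTable(pd.DataFrame(f_vals, index=f_ids, columns=samples), groups, "intensity"),
        serum=FeatureTable(pd.DataFrame(s_vals, index=s_ids, columns=samples), groups, "intensity"),
        groups=groups, truth=truth, config=config,
    )


def truth_confusion(truth_ids, reported_ids, universe) -> dict:
    """TP/FP/FN plus sensitivity and FDR of a reported feature set against
    the planted truth."""
    truth_s, rep_s, uni = set(truth_ids), set(reported_ids), set(universe)
    if not rep_s <= uni:
        raise ValueError("reported ids outside the feature universe")
    tp = len(truth_s & rep_s)
    fp = len(rep_s - truth_s)
    fn = len(truth_s - rep_s)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "sensitivity": tp / len(truth_s) if truth_s else float("nan"),
        "fdr": fp / len(rep_s) if rep_s else 0.0,
    }


def triad_confusion(truth_triads: list[dict], reported) -> dict:
    """Confusion counts for mediation triads keyed on
    (direction, x_id, m_id, y_id)."""
    truth_keys = {(t["direction"], t["x_id"], t["m_id"], t["y_id"]) for t in truth_triads}
    rep_keys = {(r.direction, r.x_id, r.m_id, r.y_id) for r in reported}
    tp = len(truth_keys & rep_keys)
    fp = len(rep_keys - truth_keys)
    fn = len(truth_keys - rep_keys)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "sensitivity": tp / len(truth_keys) if truth_keys else float("nan"),
        "fdr": fp / len(rep_keys) if rep_keys else 0.0,
    }
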