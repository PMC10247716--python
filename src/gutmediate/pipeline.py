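"""End-to-end orchestration: hormone t-tests -> microbiome screen ->
metabolome screen -> pathway enrichment -> bidirectional mediation screen.

All randomness (rarefaction, CV folds, LDA bootstraps, quasi-Bayesian
draws) flows from the single master seed via fixed per-stage offsets, so a
config + seed pair reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureTable
from .io import read_annotation, read_feature_table, read_metadata
from .mediation import (
    edge_list,
    results_to_frame,
    screen_triples,
    significant_results,
)
from .metabolome import (
    hotelling_t2_limit,
    missingness_filter,
    opls_fit,
    pathway_enrichment,
    select_differential,
    vip_select,
)
from .microbiome import (
    alpha_diversity,
    bray_curtis,
    css_normalize,
    lda_effect_screen,
    pcoa,
    rarefy,
)
from .stats_core import ttest_two_sample

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "screen_hormones"]

# fixed per-stage seed offsets off the master seed
_SEED_RAREFY, _SEED_LDA, _SEED_OPLS_F, _SEED_OPLS_S, _SEED_MEDIATE = 11, 23, 37, 41, 53


@dataclass
class PipelineConfig:
    genus_path: str
    fecal_path: str
    serum_path: str
    hormone_path: str
    metadata_path: str
    annotation_path: str | None = None
    outdir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    lda_threshold: float = 3.0
    vip_threshold: float = 1.0
    missing_frac: float = 0.6
    rarefaction_depth: int | None = None  # None -> minimum sample total
    n_ortho: int = 1
    cv_folds: int = 7
    n_sims: int = 1000
    direction: str = "both"
    require_gate: bool = True
    t_variant: str = "student"
    met_transform: str = "log10"
    treatment: str = "hypoxia"

    def __post_init__(self) -> None:
        for name in ("alpha", "lda_threshold", "vip_threshold", "missing_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class RunReport:
    version: str
    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def screen_hormones(
    hormones: FeatureTable, alpha: float = 0.05, variant: str = "student",
    positive: str = "hypoxia",
) -> pd.DataFrame:
    """Per-hormone two-tailed unpaired t-test (hypoxia vs control)."""
    other = [g for g in hormones.group_levels if g != positive][0]
    pos = hormones.group_columns(positive)
    neg = hormones.group_columns(other)
    rows = []
    for fid in hormones.feature_ids:
        res = ttest_two_sample(pos.loc[fid], neg.loc[fid], variant)
        rows.append(
            {
                "feature_id": fid,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "direction": "up" if res.statistic >= 0 else "down",
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)


def _metabolome_stage(table, cfg, seed, label, outdir, report):
    filtered, dropped = missingness_filter(table, cfg.missing_frac)
    report.counts[f"{label}_input_features"] = table.n_features
    report.counts[f"{label}_after_missingness_filter"] = filtered.n_features
    report.counts[f"{label}_dropped"] = dropped
    x = np.log10(filtered.values.to_numpy(dtype=float).T + 1.0)
    y = np.where(filtered.groups.to_numpy() == cfg.treatment, 1.0, -1.0)
    model = opls_fit(
        x, y, n_ortho=cfg.n_ortho, cv_folds=cfg.cv_folds, seed=seed,
        feature_ids=filtered.feature_ids,
    )
    t2_limit, t2 = hotelling_t2_limit(model)
    vips = vip_select(
        filtered, model, vip_threshold=cfg.vip_threshold, alpha=cfg.alpha,
        positive=cfg.treatment, transform=cfg.met_transform, t_variant=cfg.t_variant,
    )
    selected = select_differential(vips)
    report.counts[f"{label}_selected"] = len(selected)
    vips.to_csv(outdir / f"{label}_vip.tsv", sep="\t", index=False)
    summary = {
        "r2x": model.r2x, "r2y": model.r2y, "q2": model.q2,
        "n_ortho": model.n_ortho, "cv_folds": model.cv_folds,
        "hotelling_t2_limit": t2_limit,
        "hotelling_t2_outliers": [
            s for s, v in zip(filtered.sample_ids, t2) if v > t2_limit
        ],
    }
    (outdir / f"{label}_opls_summary.json").write_text(json.dumps(summary, indent=2))
    return filtered, selected


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full screen -> mediate chain, writing all stage outputs under
    ``config.outdir`` and returning the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=asdict(config), seed=config.seed)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        metadata = read_metadata(config.metadata_path)
        genus = read_feature_table(config.genus_path, "counts_tsv", metadata)
        fecal = read_feature_table(config.fecal_path, "intensity_csv", metadata)
        serum = read_feature_table(config.serum_path, "intensity_csv", metadata)
        hormones = read_feature_table(config.hormone_path, "hormone_csv", metadata)

        # stage 1: hormones
        hdiff = screen_hormones(hormones, config.alpha, config.t_variant, config.treatment)
        hdiff.to_csv(outdir / "hormones_diff.tsv", sep="\t", index=False)
        hormone_ids = set(hdiff.loc[hdiff["significant"], "feature_id"])
        report.counts["hormones_input"] = hormones.n_features
        report.counts["hormones_significant"] = len(hormone_ids)

        # stage 2: microbiome
        rare = rarefy(genus, config.rarefaction_depth, seed=config.seed + _SEED_RAREFY)
        alpha_div = alpha_diversity(rare)
        alpha_div.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        css = css_normalize(rare)
        dist = bray_curtis(css)
        dist.to_csv(outdir / "bray_curtis.tsv", sep="\t", index_label="sample_id")
        ord_res = pcoa(dist)
        coords = ord_res.coordinates.copy()
        coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
        lda = lda_effect_screen(
            rare, alpha=config.alpha, lda_threshold=config.lda_threshold,
            seed=config.seed + _SEED_LDA,
        )
        lda.to_csv(outdir / "lda_screen.tsv", sep="\t", index=False)
        genus_ids = set(lda.loc[lda["passed"], "feature_id"])
        report.counts["genera_input"] = genus.n_features
        report.counts["genera_passed_lda"] = len(genus_ids)

        # stage 3: metabolome (fecal + serum)
        fecal_f, fecal_sel = _metabolome_stage(
            fecal, config, config.seed + _SEED_OPLS_F, "fecal", outdir, report
        )
        serum_f, serum_sel = _metabolome_stage(
            serum, config, config.seed + _SEED_OPLS_S, "serum", outdir, report
        )

        # stage 4: pathway enrichment (optional annotation)
        if config.annotation_path:
            annotation = read_annotation(config.annotation_path)
            background = set(fecal_f.feature_ids) | set(serum_f.feature_ids)
            annotation = {
                pw: {m for m in members if m in background}
                for pw, members in annotation.items()
            }
            annotation = {pw: mem for pw, mem in annotation.items() if mem}
            enr = pathway_enrichment(fecal_sel | serum_sel, annotation, background)
            enr["significant"] = enr["p_value"] < config.alpha
            enr.to_csv(outdir / "pathway_enrichment.tsv", sep="\t", index=False)
            report.counts["pathways_tested"] = len(enr)
            report.counts["pathways_significant"] = int(enr["significant"].sum())

        # stage 5: mediation (combined mediator table, tagged ids)
        fvals = fecal_f.values.copy()
        fvals.index = [f"fecal:{i}" for i in fvals.index]
        svals = serum_f.values.copy()
        svals.index = [f"serum:{i}" for i in svals.index]
        mets = FeatureTable(pd.concat([fvals, svals]), metadata, "intensity")
        met_ids = {f"fecal:{i}" for i in fecal_sel} | {f"serum:{i}" for i in serum_sel}
        results, skipped = screen_triples(
            hormones, rare, mets,
            {"hormones": hormone_ids, "genera": genus_ids, "metabolites": met_ids},
            direction=config.direction, alpha=config.alpha,
            n_sims=config.n_sims, seed=config.seed + _SEED_MEDIATE,
            require_gate=config.require_gate, treatment=config.treatment,
        )
        frame = results_to_frame(results)
        frame["significant"] = frame["acme_p"] < config.alpha if len(frame) else []
        frame.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
        (outdir / "mediation_edges.json").write_text(
            json.dumps(edge_list(results, config.alpha), indent=2)
        )
        report.counts["mediation_candidate_triads"] = len(results) + len(skipped)
        report.counts["mediation_gated_triads"] = len(results)
        report.counts["mediation_significant_triads"] = len(
            significant_results(results, config.alpha)
        )

        report.warnings = [str(w.message) for w in caught]

    report.to_json(outdir / "run_report.json")
    return report
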