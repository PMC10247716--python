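"""Reading and writing the pipeline's tabular formats.

Conventions: genus counts and sample metadata travel as TSV; metabolite
intensities and the hormone panel as CSV (first column = feature id,
remaining columns = samples); pathway annotations as a two-column TSV
(pathway_id, metabolite_id per row); ground truth and reports as JSON.
Readers validate eagerly and report the offending file/feature/cell.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, TableValidationError
from .synthetic import SyntheticStudy

__all__ = [
    "read_metadata",
    "read_feature_table",
    "write_feature_table",
    "write_metadata",
    "read_annotation",
    "write_truth",
    "read_truth",
    "write_study",
]

_SCHEMAS = {
    "counts_tsv": {"sep": "\t", "kind": "counts"},
    "intensity_csv": {"sep": ",", "kind": "intensity"},
    "hormone_csv": {"sep": ",", "kind": "hormone"},
}


def read_metadata(path) -> pd.Series:
    """Sample metadata TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise TableValidationError(f"{path}: missing metadata column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableValidationError(f"{path}: duplicate sample ids {dups}")
    if df["group"].isna().any():
        bad = df.loc[df["group"].isna(), "sample_id"].tolist()
        raise TableValidationError(f"{path}: samples without group label {bad}")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def read_feature_table(path, schema: str, metadata: pd.Series) -> FeatureTable:
    """Load and validate one features x samples table.

    Sample columns are reordered to match metadata order; numeric coercion
    failures are reported with (feature, sample) coordinates.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = _SCHEMAS[schema]
    raw = pd.read_csv(path, sep=spec["sep"], index_col=0)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise TableValidationError(f"{path}: duplicate feature ids {dups}")
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableValidationError(
            f"{path}: non-numeric cell at feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if coerced.isna().to_numpy().any():
        i, j = np.argwhere(coerced.isna().to_numpy())[0]
        raise TableValidationError(
            f"{path}: empty cell at feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    extra = [s for s in coerced.columns if s not in metadata.index]
    missing = [s for s in metadata.index if s not in coerced.columns]
    if extra or missing:
        raise TableValidationError(
            f"{path}: sample mismatch vs metadata (extra={extra}, missing={missing})"
        )
    coerced = coerced[list(metadata.index)]
    return FeatureTable(coerced, metadata, spec["kind"])


def write_feature_table(table: FeatureTable, path) -> None:
    sep = "\t" if table.kind == "counts" else ","
    table.values.to_csv(path, sep=sep, index_label="feature_id")


def write_metadata(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> dict[str, set[str]]:
    """Pathway annotation TSV (pathway_id, metabolite_id) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pathway_id", "metabolite_id"):
        if col not in df.columns:
            raise TableValidationError(f"{path}: missing annotation column {col!r}")
    out: dict[str, set[str]] = {}
    for pw, mid in zip(df["pathway_id"], df["metabolite_id"]):
        out.setdefault(pw, set()).add(mid)
    return out


def write_truth(truth, path) -> None:
    payload = {
        "diff_hormones": sorted(truth.diff_hormones),
        "diff_genera": sorted(truth.diff_genera),
        "diff_fecal": sorted(truth.diff_fecal),
        "diff_serum": sorted(truth.diff_serum),
        "triads": truth.triads,
        "library_sizes": truth.library_sizes.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write a generated study's tables, metadata and truth to ``outdir``;
    returns the file map used by the pipeline config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genus": outdir / "genus_counts.tsv",
        "fecal": outdir / "fecal_intensities.csv",
        "serum": outdir / "serum_intensities.csv",
        "hormones": outdir / "hormones.csv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_feature_table(study.genus, paths["genus"])
    write_feature_table(study.fecal, paths["fecal"])
    write_feature_table(study.serum, paths["serum"])
    write_feature_table(study.hormones, paths["hormones"])
    write_metadata(study.groups, paths["metadata"])
    write_truth(study.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
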