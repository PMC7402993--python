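"""File-format plumbing: cohort CSV schema, model YAML, run artifacts.

Interchange formats are deliberately plain: tidy CSV for cohorts, exclusion
logs and reference tables; YAML for configurations and fitted models, so
every artifact is human-diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lms_core import LMSModel
from .stratified import ReferenceSet
from .synthetic_cohort import CohortConfig, TrueCurveSet

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "model_to_yaml",
    "model_from_yaml",
    "write_reference_set",
]

log = logging.getLogger("lmsref")

#: required columns of a cohort CSV, with units
COHORT_COLUMNS = {
    "subject_id": str,
    "sex": str,  # male | female
    "age": float,  # years
    "height": float,  # cm
    "weight": float,  # kg
    "fm_total": float,  # kg
    "fm_trunk": float,
    "fm_limbs": float,
    "fm_android": float,
    "fm_gynoid": float,
    "lm_total": float,
    "lm_limbs": float,
    "vat_mass": float,  # g
    "vat_volume": float,  # cm^3
    "pregnant_or_breastfeeding": bool,
}

_MASS_COLUMNS = [
    "height", "weight", "fm_total", "fm_trunk", "fm_limbs",
    "fm_android", "fm_gynoid", "lm_total", "lm_limbs", "vat_mass", "vat_volume",
]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; malformed rows reported by line number."""
    import warnings

    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty cohort file", UserWarning)
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    if len(df) == 0:
        warnings.warn(f"{path}: empty cohort file", UserWarning)
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_lines = []
    for col in _MASS_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        # header is line 1, first data row line 2
        bad_lines.extend((int(i) + 2, col) for i in df.index[bad])
        df[col] = vals
    bad_sex = ~df["sex"].isin(["male", "female"])
    bad_lines.extend((int(i) + 2, "sex") for i in df.index[bad_sex])
    if bad_lines:
        desc = "; ".join(f"line {ln}: invalid {col}" for ln, col in bad_lines[:10])
        raise ValueError(f"{path}: {len(bad_lines)} malformed value(s): {desc}")
    df["pregnant_or_breastfeeding"] = df["pregnant_or_breastfeeding"].astype(bool)
    return df


def write_cohort_csv(
    cohort: pd.DataFrame,
    path,
    config: CohortConfig | None = None,
    curves: dict[tuple[str, str], TrueCurveSet] | None = None,
) -> None:
    """Write a cohort CSV plus (optionally) a sidecar YAML with the generating
    configuration and true-curve coefficients."""
    path = Path(path)
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    extra = [c for c in cohort.columns if c not in cols]
    cohort[cols + extra].to_csv(path, index=False)
    if config is not None or curves is not None:
        sidecar = {}
        if config is not None:
            sidecar["config"] = config.to_dict()
        if curves is not None:
            sidecar["true_curves"] = [c.to_dict() for c in curves.values()]
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=False)


def model_to_yaml(model: LMSModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def model_from_yaml(path) -> LMSModel:
    with open(path) as fh:
        return LMSModel.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_reference_set(ref: ReferenceSet, outdir) -> dict:
    """Persist a ReferenceSet as models/*.yaml, tables/*.csv, reports/*.yaml
    plus a manifest with content hashes; returns the manifest."""
    outdir = Path(outdir)
    for sub in ("models", "tables", "reports"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    manifest = {"models": {}, "tables": {}, "reports": {}, "provenance": ref.provenance}
    for (param, sex, stratum), model in sorted(ref.models.items()):
        stem = f"{param}_{sex}_{stratum}"
        mpath = outdir / "models" / f"{stem}.yaml"
        model_to_yaml(model, mpath)
        manifest["models"][stem] = {
            "df": list(model.df),
            "bic": float(model.bic),
            "sha256": _sha256(mpath),
        }
        if (param, sex, stratum) in ref.tables:
            tpath = outdir / "tables" / f"{stem}.csv"
            ref.tables[(param, sex, stratum)].to_csv(tpath)
            manifest["tables"][stem] = {"sha256": _sha256(tpath)}
        if (param, sex, stratum) in ref.reports:
            rpath = outdir / "reports" / f"{stem}.yaml"
            with open(rpath, "w") as fh:
                yaml.safe_dump(ref.reports[(param, sex, stratum)].to_dict(), fh)
            manifest["reports"][stem] = {"sha256": _sha256(rpath)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
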