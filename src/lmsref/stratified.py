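"""End-to-end reference construction: per-sex models, FMI and BMI strata.

`build_reference_set` fits one LMS model per parameter and sex (gross-outlier
screen, BIC selection over a degrees-of-freedom grid, reference table,
adequacy report).  `fmi_stratified_lmi` re-fits the lean-mass index within
fat-mass strata defined by the FMI model's own age-specific 25th and 75th
percentiles (low: <= P25, normal: between, high: >= P75).
`bmi_stratified_lm` re-fits the lean-mass indices within WHO BMI categories
(underweight excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .centiles import DEFAULT_PERCENTILES, ReferenceTable, make_reference_table
from .lms_core import FitData, LMSModel, compute_z, exclude_outliers, select_model
from .validation import ValidationReport, validate_reference_set

__all__ = [
    "FitConfig",
    "ReferenceSet",
    "build_reference_set",
    "assign_fmi_stratum",
    "fmi_stratified_lmi",
    "bmi_stratified_lm",
]

FMI_STRATA = ("low", "normal", "high")


@dataclass
class FitConfig:
    """Knobs of the reference-construction pipeline."""

    df_grid: list[tuple[int, int, int]] | None = None
    age_domain: tuple[float, float] = (18.0, 82.0)
    outlier_threshold: float = 10.0
    percentiles: tuple = DEFAULT_PERCENTILES
    age_grid: np.ndarray | None = None
    min_stratum_n: int = 200
    fmi_split: str = "model"  # age-specific model percentiles; or "marginal"

    def __post_init__(self):
        if self.fmi_split not in ("model", "marginal"):
            raise ValueError("fmi_split must be 'model' or 'marginal'")


@dataclass
class ReferenceSet:
    """Fitted models, reference tables and reports, keyed (parameter, sex, stratum)."""

    models: dict[tuple[str, str, str], LMSModel] = field(default_factory=dict)
    tables: dict[tuple[str, str, str], ReferenceTable] = field(default_factory=dict)
    reports: dict[tuple[str, str, str], ValidationReport] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _fit_one(t, y, parameter, sex, stratum, config: FitConfig):
    data = FitData(np.asarray(t, float), np.asarray(y, float))
    data, removed = exclude_outliers(data, config.outlier_threshold)
    model = select_model(
        data,
        config.df_grid,
        domain=config.age_domain,
        parameter_name=parameter,
        sex=sex,
        stratum=stratum,
    )
    table = make_reference_table(model, config.age_grid, config.percentiles)
    return data, model, table, {"n_outliers_removed": int(len(removed))}


def build_reference_set(
    cohort: pd.DataFrame,
    parameters,
    config: FitConfig | None = None,
) -> ReferenceSet:
    """Fit per-sex LMS models for each parameter of an (already filtered) cohort.

    The cohort must carry index columns (see ``indices.compute_indices``).
    Strata (here: sexes) with fewer than ``config.min_stratum_n`` eligible
    subjects are skipped with a warning.  Deterministic given cohort and
    config.
    """
    config = config or FitConfig()
    ref = ReferenceSet(provenance={"parameters": list(parameters), "skipped": []})
    fit_inputs: dict[tuple[str, str], FitData] = {}
    for parameter in parameters:
        for sex in ("male", "female"):
            sub = cohort[(cohort["sex"] == sex) & np.isfinite(cohort[parameter])]
            if len(sub) < config.min_stratum_n:
                warnings.warn(
                    f"skipping {parameter}/{sex}: only {len(sub)} subjects "
                    f"(minimum {config.min_stratum_n})",
                    UserWarning,
                )
                ref.provenance["skipped"].append([parameter, sex, "all"])
                continue
            data, model, table, prov = _fit_one(
                sub["age"].to_numpy(), sub[parameter].to_numpy(),
                parameter, sex, "all", config,
            )
            key = (parameter, sex, "all")
            ref.models[key] = model
            ref.tables[key] = table
            fit_inputs[(parameter, sex)] = data
            ref.provenance[f"{parameter}/{sex}"] = {
                "df_selected": list(model.df),
                "bic": model.bic,
                "n_fit": model.n_fit,
                **prov,
            }
    pair_models = {(p, s): m for (p, s, _), m in ref.models.items()}
    reports = validate_reference_set(pair_models, fit_inputs, config.percentiles)
    for rep in reports:
        ref.reports[(rep.parameter_name, rep.sex, "all")] = rep
    return ref


def assign_fmi_stratum(
    cohort: pd.DataFrame,
    fmi_models: dict[str, LMSModel],
    mode: str = "model",
) -> pd.Series:
    """Label each subject low / normal / high fat-mass index.

    ``mode='model'`` uses the FMI model's age-specific percentiles: low means
    the subject's FMI is at or below the age-specific 25th percentile
    (z <= z_0.25), high means at or above the 75th (z >= z_0.75).
    ``mode='marginal'`` uses the sex-wise unconditional sample quartiles.
    """
    out = pd.Series(index=cohort.index, dtype=object)
    z25 = _sps.norm.ppf(0.25)
    z75 = _sps.norm.ppf(0.75)
    for sex in cohort["sex"].unique():
        mask = cohort["sex"] == sex
        fmi = cohort.loc[mask, "fmi"].to_numpy(dtype=float)
        if mode == "model":
            model = fmi_models[sex]
            z = compute_z(fmi, cohort.loc[mask, "age"].to_numpy(dtype=float), model)
            # tiny tolerance keeps subjects exactly on a boundary centile on
            # the side the rule assigns them (low: <= P25, high: >= P75)
            eps = 1e-9
            lo, hi = z <= z25 + eps, z >= z75 - eps
        elif mode == "marginal":
            q25, q75 = np.quantile(fmi, [0.25, 0.75])
            lo, hi = fmi <= q25, fmi >= q75
        else:
            raise ValueError("mode must be 'model' or 'marginal'")
        lab = np.where(lo, "low", np.where(hi, "high", "normal"))
        out.loc[mask] = lab
    return out


def fmi_stratified_lmi(
    cohort: pd.DataFrame,
    fmi_models: dict[str, LMSModel],
    config: FitConfig | None = None,
) -> ReferenceSet:
    """LMI models within low/normal/high FMI strata, per sex."""
    config = config or FitConfig()
    strata = assign_fmi_stratum(cohort, fmi_models, config.fmi_split)
    ref = ReferenceSet(provenance={"stratification": "fmi", "skipped": []})
    fit_inputs = {}
    for sex in ("male", "female"):
        for stratum in FMI_STRATA:
            sub = cohort[(cohort["sex"] == sex) & (strata == stratum)]
            if len(sub) < config.min_stratum_n:
                warnings.warn(
                    f"skipping lmi/{sex}/{stratum}: only {len(sub)} subjects",
                    UserWarning,
                )
                ref.provenance["skipped"].append(["lmi", sex, stratum])
                continue
            data, model, table, prov = _fit_one(
                sub["age"].to_numpy(), sub["lmi"].to_numpy(),
                "lmi", sex, stratum, config,
            )
            key = ("lmi", sex, stratum)
            ref.models[key] = model
            ref.tables[key] = table
            fit_inputs[key] = data
            ref.provenance[f"lmi/{sex}/{stratum}"] = {
                "df_selected": list(model.df),
                "n_fit": model.n_fit,
                **prov,
            }
    pair = {(f"lmi[{k[2]}]", k[1]): m for k, m in ref.models.items()}
    data_pair = {(f"lmi[{k[2]}]", k[1]): d for k, d in fit_inputs.items()}
    for rep in validate_reference_set(pair, data_pair, config.percentiles):
        name, stratum = rep.parameter_name.split("[")
        ref.reports[(name, rep.sex, stratum.rstrip("]"))] = rep
    return ref


def bmi_stratified_lm(
    cohort: pd.DataFrame,
    config: FitConfig | None = None,
    parameters=("lmi", "appendicular_lmi"),
) -> ReferenceSet:
    """Lean-mass index models within WHO BMI categories, per sex.

    Underweight subjects are excluded from modelling (mirroring the
    reference study, whose underweight stratum was too small).
    """
    config = config or FitConfig()
    categories = ("normal", "overweight", "obese")
    ref = ReferenceSet(provenance={"stratification": "bmi", "skipped": []})
    fit_inputs = {}
    for parameter in parameters:
        for sex in ("male", "female"):
            for cat in categories:
                sub = cohort[
                    (cohort["sex"] == sex) & (cohort["bmi_category"] == cat)
                ]
                if len(sub) < config.min_stratum_n:
                    warnings.warn(
                        f"skipping {parameter}/{sex}/{cat}: only {len(sub)} subjects",
                        UserWarning,
                    )
                    ref.provenance["skipped"].append([parameter, sex, cat])
                    continue
                data, model, table, prov = _fit_one(
                    sub["age"].to_numpy(), sub[parameter].to_numpy(),
                    parameter, sex, cat, config,
                )
                key = (parameter, sex, cat)
                ref.models[key] = model
                ref.tables[key] = table
                fit_inputs[key] = data
                ref.provenance[f"{parameter}/{sex}/{cat}"] = {
                    "df_selected": list(model.df),
                    "n_fit": model.n_fit,
                    **prov,
                }
    pair = {(f"{k[0]}[{k[2]}]", k[1]): m for k, m in ref.models.items()}
    data_pair = {(f"{k[0]}[{k[2]}]", k[1]): d for k, d in fit_inputs.items()}
    for rep in validate_reference_set(pair, data_pair, config.percentiles):
        name, stratum = rep.parameter_name.split("[")
        ref.reports[(name, rep.sex, stratum.rstrip("]"))] = rep
    return ref
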