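"""Derived body-composition indices, eligibility filters, and group labels.

Index definitions (heights in cm are converted to m):

* BMI  = weight / height^2            (kg/m^2)
* FMI  = fat mass / height^2          (kg/m^2)
* LMI  = lean mass / height^2         (kg/m^2)
* appendicular LMI/FMI = limb lean/fat mass / height^2
* FM trunk/limbs   = trunk fat mass / limb fat mass
* FM android/gynoid = android fat mass / gynoid fat mass
* %FM = 100 * fat mass / body weight; %LM = 100 - %FM

Eligibility filters mirror the reference study: pregnant or breastfeeding
subjects are excluded; body weight strictly above the scanner limit of
159 kg is excluded; VAT analyses additionally require BMI within
[18.5, 40] kg/m^2.  Ages are restricted to [18, 82).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUP_EDGES",
    "BMI_CATEGORIES",
    "compute_indices",
    "apply_exclusions",
    "assign_age_group",
    "assign_bmi_category",
    "coefficient_of_variation",
]

AGE_GROUP_EDGES = [18.0, 30.0, 40.0, 50.0, 60.0, 70.0, 82.0]
AGE_GROUP_LABELS = [
    "18 to <30",
    "30 to <40",
    "40 to <50",
    "50 to <60",
    "60 to <70",
    "70 to <82",
]

#: WHO categories; underweight is flagged for exclusion from lean-mass models
BMI_CATEGORIES = ["underweight", "normal", "overweight", "obese"]

WEIGHT_LIMIT_KG = 159.0
VAT_BMI_RANGE = (18.5, 40.0)


def assign_age_group(age):
    """Decade-style age-group label; half-open intervals [a, b)."""
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(~np.isfinite(age_arr)) or np.any(age_arr < 18.0) or np.any(age_arr >= 82.0):
        raise ValueError("age must lie in [18, 82)")
    idx = np.searchsorted(AGE_GROUP_EDGES, age_arr, side="right") - 1
    labels = np.array(AGE_GROUP_LABELS, dtype=object)[idx]
    return labels[0] if np.ndim(age) == 0 else labels


def assign_bmi_category(bmi):
    """WHO BMI category: underweight <18.5, normal, overweight, obese >=30."""
    bmi_arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    if np.any(~np.isfinite(bmi_arr)) or np.any(bmi_arr <= 0):
        raise ValueError("bmi must be finite and positive")
    labels = np.select(
        [bmi_arr < 18.5, bmi_arr < 25.0, bmi_arr < 30.0],
        ["underweight", "normal", "overweight"],
        default="obese",
    ).astype(object)
    return labels[0] if np.ndim(bmi) == 0 else labels


def compute_indices(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add derived index columns to a cohort of raw records.

    Requires positive heights and positive ratio denominators (limb and
    gynoid fat masses); raises ``ValueError`` naming the offending field.
    """
    df = cohort.copy()
    if len(df) == 0:
        for col in (
            "bmi", "fmi", "lmi", "appendicular_lmi", "appendicular_fmi",
            "fm_trunk_limbs", "fm_android_gynoid", "pct_fm", "pct_lm",
            "age_group", "bmi_category",
        ):
            df[col] = pd.Series(dtype=float if col not in ("age_group", "bmi_category") else object)
        return df
    if np.any(df["height"].to_numpy() <= 0):
        raise ValueError("height must be positive")
    for fieldname in ("fm_limbs", "fm_gynoid"):
        if np.any(df[fieldname].to_numpy() <= 0):
            raise ValueError(f"{fieldname} must be positive (ratio denominator)")
    h_m2 = (df["height"].to_numpy() / 100.0) ** 2
    df["bmi"] = df["weight"] / h_m2
    df["fmi"] = df["fm_total"] / h_m2
    df["lmi"] = df["lm_total"] / h_m2
    df["appendicular_lmi"] = df["lm_limbs"] / h_m2
    df["appendicular_fmi"] = df["fm_limbs"] / h_m2
    df["fm_trunk_limbs"] = df["fm_trunk"] / df["fm_limbs"]
    df["fm_android_gynoid"] = df["fm_android"] / df["fm_gynoid"]
    df["pct_fm"] = 100.0 * df["fm_total"] / df["weight"]
    df["pct_lm"] = 100.0 - df["pct_fm"]
    df["age_group"] = assign_age_group(df["age"].to_numpy())
    df["bmi_category"] = assign_bmi_category(df["bmi"].to_numpy())
    return df


def apply_exclusions(cohort: pd.DataFrame, purpose: str = "body_composition"):
    """Apply the study's eligibility filters.

    ``purpose='body_composition'`` removes pregnant/breastfeeding subjects,
    body weight strictly above 159 kg, and ages outside [18, 82);
    ``purpose='vat'`` additionally removes BMI outside [18.5, 40].  Returns
    ``(filtered cohort, exclusion log)`` where the log has one row per
    (subject, rule fired).
    """
    if purpose not in ("body_composition", "vat"):
        raise ValueError(f"unknown purpose {purpose!r}")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    df = cohort
    rules: dict[str, np.ndarray] = {}
    preg = df.get("pregnant_or_breastfeeding")
    if preg is not None:
        rules["pregnancy_breastfeeding"] = preg.to_numpy().astype(bool)
    rules["weight_gt_159"] = df["weight"].to_numpy() > WEIGHT_LIMIT_KG
    age = df["age"].to_numpy(dtype=float)
    rules["age_out_of_range"] = (age < 18.0) | (age >= 82.0)
    if purpose == "vat":
        if "bmi" in df.columns:
            bmi = df["bmi"].to_numpy(dtype=float)
        else:
            bmi = df["weight"].to_numpy() / (df["height"].to_numpy() / 100.0) ** 2
        lo, hi = VAT_BMI_RANGE
        rules["vat_bmi_out_of_range"] = (bmi < lo) | (bmi > hi)

    excluded = np.zeros(len(df), dtype=bool)
    log_rows = []
    ids = df["subject_id"].to_numpy()
    for rule, mask in rules.items():
        excluded |= mask
        for sid in ids[mask]:
            log_rows.append({"subject_id": sid, "rule_fired": rule, "retained": False})
    log = pd.DataFrame(log_rows, columns=["subject_id", "rule_fired", "retained"])
    return df.loc[~excluded].copy(), log


def coefficient_of_variation(replicate_sds, replicate_means) -> float:
    """Precision %CV: root-mean-square SD divided by the mean of means, x100."""
    sds = np.asarray(replicate_sds, dtype=float)
    means = np.asarray(replicate_means, dtype=float)
    if sds.size == 0 or means.size == 0:
        raise ValueError("replicate lists must be non-empty")
    if sds.shape != means.shape:
        raise ValueError("replicate lists must have the same length")
    if np.any(means <= 0):
        raise ValueError("replicate means must be positive")
    return float(100.0 * np.sqrt(np.mean(sds**2)) / np.mean(means))
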