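"""Centile curves, reference tables, and value/z/percentile conversions.

A fitted LMS model defines, at every age in its domain, a full reference
distribution; the p-th centile curve is the age trajectory of that
distribution's p-quantile, obtained by inverting the Box-Cox z-transform at
the standard-normal quantile z_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lms_core import (
    LOGNORMAL_L_THRESHOLD,
    LMSModel,
    bccg_inverse_z,
    compute_z,
)

__all__ = [
    "DEFAULT_PERCENTILES",
    "ReferenceTable",
    "centile_value",
    "make_reference_table",
    "zscore_cohort",
]

#: the percentiles printed in the published reference tables
DEFAULT_PERCENTILES = (3, 10, 50, 90, 97)


def centile_value(p, t, model: LMSModel):
    """Measurement value at probability ``p`` and age ``t`` under the model.

    ``y = M(t) * (1 + L(t)*S(t)*z_p)**(1/L(t))`` with ``z_p`` the
    standard-normal quantile (lognormal branch for ``|L| < 1e-5``).  Raises
    if the requested percentile lies outside the attainable range of the
    Box-Cox transform, reporting that range.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie strictly between 0 and 1")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    L, M, S = model._curves_at(t_arr)
    zp = stats.norm.ppf(p_arr)
    base = 1.0 + L * S * zp
    big = np.abs(L) >= LOGNORMAL_L_THRESHOLD
    if np.any(big & (base <= 0)):
        i = int(np.argmax(big & (base <= 0)))
        bound = stats.norm.cdf(-1.0 / (L[i] * S[i]))
        lo, hi = (bound, 1.0) if L[i] * S[i] > 0 else (0.0, 1.0 - bound)
        raise ValueError(
            f"percentile {p_arr[i]:.4f} unattainable at age {t_arr[i]:g}: "
            f"attainable range is ({lo:.6f}, {hi:.6f})"
        )
    y = bccg_inverse_z(zp, L, M, S)
    y = np.atleast_1d(y)
    if np.ndim(p) == 0 and np.ndim(t) == 0:
        return float(y[0])
    return y


@dataclass
class ReferenceTable:
    """Age grid x (L, M, S, percentile) values for one parameter/sex/stratum."""

    parameter_name: str
    sex: str
    stratum: str
    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")


def make_reference_table(
    model: LMSModel,
    age_grid=None,
    percentiles=DEFAULT_PERCENTILES,
) -> ReferenceTable:
    """Tabulate L, M, S and centile values on an age grid.

    Default grid: integer ages 18..81 (clipped to the model domain is NOT
    done -- a grid point outside the domain raises).
    """
    if age_grid is None:
        age_grid = np.arange(18.0, 82.0, 1.0)
    ages = np.asarray(age_grid, dtype=float)
    L, M, S = model._curves_at(ages)  # raises DomainError outside domain
    cols = {"age": ages, "L": L, "M": M, "S": S}
    for p in percentiles:
        cols[f"P{p:g}"] = centile_value(p / 100.0, ages, model)
    frame = pd.DataFrame(cols)
    pcols = [f"P{p:g}" for p in sorted(percentiles)]
    vals = frame[pcols].to_numpy()
    if np.any(np.diff(vals, axis=1) <= 0):
        raise AssertionError("centile columns are not strictly increasing")
    return ReferenceTable(model.parameter_name, model.sex, model.stratum, frame)


def zscore_cohort(
    cohort: pd.DataFrame,
    models: dict[tuple[str, str], LMSModel],
    parameters=None,
) -> pd.DataFrame:
    """Per-subject z-scores for each parameter under per-sex models.

    ``models`` maps ``(parameter_name, sex)`` to a fitted model.  Missing
    measurements propagate as NaN; a missing model for a requested
    parameter/sex raises ``KeyError``.
    """
    if parameters is None:
        parameters = sorted({p for p, _ in models})
    out = pd.DataFrame(index=cohort.index)
    if "subject_id" in cohort.columns:
        out["subject_id"] = cohort["subject_id"]
    if len(cohort) == 0:
        for p in parameters:
            out[f"z_{p}"] = pd.Series(dtype=float)
        return out
    sexes = cohort["sex"].unique()
    for p in parameters:
        col = np.full(len(cohort), np.nan)
        for s in sexes:
            if (p, s) not in models:
                raise KeyError(f"no model for parameter {p!r}, sex {s!r}")
            mask = (cohort["sex"] == s).to_numpy()
            y = cohort.loc[mask, p].to_numpy(dtype=float)
            t = cohort.loc[mask, "age"].to_numpy(dtype=float)
            finite = np.isfinite(y)
            z = np.full(y.shape, np.nan)
            if finite.any():
                z[finite] = compute_z(y[finite], t[finite], models[(p, s)])
            col[mask] = z
        out[f"z_{p}"] = col
    return out
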