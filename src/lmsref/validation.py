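"""Model-adequacy diagnostics for fitted reference models.

Two checks mirror standard reference-curve practice: (1) the empirical
fraction of data points lying strictly below each centile curve should match
the nominal probability; (2) z-scores computed from the fitted L/M/S curves
should follow a standard normal distribution (one-sample Kolmogorov-Smirnov
test, with Holm correction across the family of parameter-by-sex tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .group_testing import holm_adjust
from .lms_core import FitData, LMSModel, compute_z, _as_fitdata
from .centiles import DEFAULT_PERCENTILES, centile_value

__all__ = [
    "ValidationReport",
    "coverage_below_centiles",
    "ks_normality",
    "validate_reference_set",
]

#: default tolerance on centile coverage, in percentage points
COVERAGE_TOL_PCT_POINTS = 2.0


def coverage_below_centiles(
    data,
    model: LMSModel,
    percentiles=DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """Fraction of observations strictly below each centile curve.

    Points exactly on a curve count as not below.
    """
    data = _as_fitdata(data)
    if len(data) == 0:
        raise ValueError("data is empty")
    if len(data) < 100:
        raise ValueError("need at least 100 observations for coverage checks")
    rows = []
    for p in percentiles:
        curve = centile_value(p / 100.0, data.t, model)
        frac = float(np.mean(data.y < curve))
        rows.append({"percentile": float(p), "fraction_below": frac})
    return pd.DataFrame(rows, columns=["percentile", "fraction_below"])


def ks_normality(zscores) -> tuple[float, float]:
    """One-sample two-sided Kolmogorov-Smirnov test of z-scores vs N(0, 1)."""
    z = np.asarray(zscores, dtype=float)
    if z.size < 20:
        raise ValueError("need at least 20 z-scores")
    if np.any(~np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    if np.allclose(z, z[0]):
        raise ValueError("z-scores are constant")
    res = stats.kstest(z, "norm", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ValidationReport:
    """Adequacy diagnostics for one fitted model."""

    parameter_name: str
    sex: str
    stratum: str
    coverage: pd.DataFrame
    ks_statistic: float
    ks_p: float
    ks_p_adjusted: float = float("nan")
    ks_pass: bool = False
    coverage_pass: bool = False

    @property
    def passed(self) -> bool:
        return self.ks_pass and self.coverage_pass

    def to_dict(self) -> dict:
        return {
            "parameter_name": self.parameter_name,
            "sex": self.sex,
            "stratum": self.stratum,
            "coverage": {
                f"P{row.percentile:g}": float(row.fraction_below)
                for row in self.coverage.itertuples()
            },
            "ks_statistic": float(self.ks_statistic),
            "ks_p": float(self.ks_p),
            "ks_p_adjusted": float(self.ks_p_adjusted),
            "ks_pass": bool(self.ks_pass),
            "coverage_pass": bool(self.coverage_pass),
            "passed": bool(self.passed),
        }


def validate_reference_set(
    models: dict[tuple[str, str], LMSModel],
    data: dict[tuple[str, str], FitData],
    percentiles=DEFAULT_PERCENTILES,
    alpha: float = 0.05,
    coverage_tol: float = COVERAGE_TOL_PCT_POINTS,
) -> list[ValidationReport]:
    """Validate a family of models against their fitting data.

    KS p-values are Holm-adjusted across all parameter-by-sex tests; a model
    passes if its adjusted KS p is >= ``alpha`` and every coverage fraction
    is within ``coverage_tol`` percentage points of nominal.
    """
    if set(models) != set(data):
        raise ValueError("models and data must be keyed by the same (parameter, sex) pairs")
    keys = sorted(models)
    if not keys:
        return []
    reports = []
    pvals = []
    for key in keys:
        model = models[key]
        d = _as_fitdata(data[key])
        z = compute_z(d.y, d.t, model)
        stat, p = ks_normality(z)
        cov = coverage_below_centiles(d, model, percentiles)
        reports.append(
            ValidationReport(
                parameter_name=key[0],
                sex=key[1],
                stratum=model.stratum,
                coverage=cov,
                ks_statistic=stat,
                ks_p=p,
            )
        )
        pvals.append(p)
    adjusted = holm_adjust(pvals)
    for rep, padj in zip(reports, adjusted):
        rep.ks_p_adjusted = float(padj)
        rep.ks_pass = bool(padj >= alpha)
        dev = np.abs(
            rep.coverage["fraction_below"].to_numpy() * 100.0
            - rep.coverage["percentile"].to_numpy()
        )
        rep.coverage_pass = bool(np.all(dev <= coverage_tol))
    return reports
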