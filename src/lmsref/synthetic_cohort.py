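"""Synthetic DXA cohort generator.

The reference study's raw cohort is not public, so every downstream stage is
exercised on simulated cohorts drawn from known age-dependent Box-Cox
Cole-Green (BCCG) distributions.  For each body-composition parameter and sex
a :class:`TrueCurveSet` holds generating curves L(t), M(t), S(t) over ages
[18, 82); the default curves interpolate the published age-group means
(median curve) and coefficients of variation (S curve) of the reference
cohort, so simulated cohorts resemble the study population in location and
spread.

Joint structure across parameters is a Gaussian copula on the latent
z-scores.  Six parameters are sampled directly (FMI, LMI, appendicular LMI,
FM android/gynoid, FM trunk/limbs, VAT mass); appendicular FMI is derived
structurally from total fat, the trunk/limbs ratio and a small head-fat
share, because total, trunk and limb fat are tied by an additive identity
that leaves no room for a seventh free margin (see docs/methods.md).
Regional masses are assembled so that every generated record satisfies the
anatomical invariants (fm_trunk + fm_limbs <= fm_total, lm_limbs <=
lm_total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from . import table1
from .lms_core import LOGNORMAL_L_THRESHOLD

__all__ = [
    "SUPPORTED_PARAMETERS",
    "SAMPLED_PARAMETERS",
    "TrueCurveSet",
    "CohortConfig",
    "default_true_curves",
    "default_curve_library",
    "sample_measurement",
    "generate_cohort",
]

#: parameters with built-in generating curves
SUPPORTED_PARAMETERS = table1.REFERENCE_PARAMETERS

#: parameters drawn directly from their BCCG curves via the copula
SAMPLED_PARAMETERS = (
    "fmi",
    "lmi",
    "appendicular_lmi",
    "fm_android_gynoid",
    "fm_trunk_limbs",
    "vat_mass",
)

#: constant Box-Cox powers of the generating distributions. Lean-mass indices
#: are close to symmetric (L near 1); fat measures are right-skewed, VAT
#: strongly so.
_DEFAULT_L = {
    "fmi": 0.3,
    "lmi": 1.0,
    "appendicular_lmi": 1.0,
    "appendicular_fmi": 0.4,
    "fm_android_gynoid": 0.5,
    "fm_trunk_limbs": 0.5,
    "vat_mass": 0.15,
}

#: adipose tissue density (g/cm^3) used to convert VAT mass to volume; the
#: published mass/volume means have ratio ~0.943
VAT_DENSITY_G_PER_CM3 = 0.94

AGE_DOMAIN = (18.0, 82.0)


@dataclass(frozen=True)
class TrueCurveSet:
    """Generating L/M/S curves of one parameter for one sex.

    Curves are monotone-preserving cubic (PCHIP) interpolants through values
    at fixed knot ages spanning [18, 82); M and S are positive everywhere by
    construction.
    """

    parameter_name: str
    sex: str
    knot_ages: tuple[float, ...]
    L_values: tuple[float, ...]
    M_values: tuple[float, ...]
    S_values: tuple[float, ...]

    def __post_init__(self):
        if any(v <= 0 for v in self.M_values) or any(v <= 0 for v in self.S_values):
            raise ValueError("M and S curve values must be positive")

    def _interp(self, values):
        return PchipInterpolator(np.asarray(self.knot_ages), np.asarray(values))

    def L_curve(self, t):
        return self._interp(self.L_values)(t)

    def M_curve(self, t):
        return self._interp(self.M_values)(t)

    def S_curve(self, t):
        return self._interp(self.S_values)(t)

    def to_dict(self) -> dict:
        return {
            "parameter_name": self.parameter_name,
            "sex": self.sex,
            "knot_ages": list(self.knot_ages),
            "L_values": list(self.L_values),
            "M_values": list(self.M_values),
            "S_values": list(self.S_values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueCurveSet":
        return cls(
            d["parameter_name"],
            d["sex"],
            tuple(d["knot_ages"]),
            tuple(d["L_values"]),
            tuple(d["M_values"]),
            tuple(d["S_values"]),
        )


def default_true_curves(sex: str, parameter_name: str) -> TrueCurveSet:
    """Built-in generating curves calibrated to the published age-group stats.

    The median curve passes exactly through the published group means at the
    age-group midpoints (flat beyond the outermost midpoints); the S curve
    interpolates the published group SD/mean ratios.  Deterministic.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}: expected 'male' or 'female'")
    if parameter_name not in SUPPORTED_PARAMETERS:
        raise ValueError(
            f"unknown parameter {parameter_name!r}: supported are "
            f"{', '.join(SUPPORTED_PARAMETERS)}"
        )
    stats_ = table1.GROUP_STATS[sex][parameter_name]
    mids = table1.AGE_GROUP_MIDPOINTS
    means = [m for m, _ in stats_]
    cvs = [sd / m for m, sd in stats_]

    def extend(vals):
        # linear extrapolation to the domain edges keeps the curves smooth
        # (no curvature kink at the outer midpoints); floored for positivity
        lo = vals[0] + (vals[1] - vals[0]) / (mids[1] - mids[0]) * (AGE_DOMAIN[0] - mids[0])
        hi = vals[-1] + (vals[-1] - vals[-2]) / (mids[-1] - mids[-2]) * (AGE_DOMAIN[1] - mids[-1])
        return [max(lo, 0.5 * vals[0])] + list(vals) + [max(hi, 0.5 * vals[-1])]

    knots = tuple([AGE_DOMAIN[0]] + mids + [AGE_DOMAIN[1]])
    M_vals = tuple(extend(means))
    S_vals = tuple(extend(cvs))
    L = _DEFAULT_L[parameter_name]
    L_vals = tuple([L] * len(knots))
    return TrueCurveSet(parameter_name, sex, knots, L_vals, M_vals, S_vals)


def default_curve_library() -> dict[tuple[str, str], TrueCurveSet]:
    """All built-in curve sets, keyed by (parameter_name, sex)."""
    return {
        (p, s): default_true_curves(s, p)
        for p in SUPPORTED_PARAMETERS
        for s in ("male", "female")
    }


def sample_measurement(curves: TrueCurveSet, t, z):
    """Measurement value at age ``t`` and latent standard-normal deviate ``z``.

    Inverts the Box-Cox z-transform: ``y = M * (1 + L*S*z)**(1/L)``, with the
    lognormal branch ``y = M * exp(S*z)`` for ``|L| < 1e-5``.  Requires
    ``1 + L*S*z > 0``; callers implementing truncated sampling must resample
    z on violation.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z must be finite")
    a, b = AGE_DOMAIN
    if np.any(t < curves.knot_ages[0]) or np.any(t > curves.knot_ages[-1]):
        raise ValueError("age outside curve domain")
    L = np.asarray(curves.L_curve(t), dtype=float)
    M = np.asarray(curves.M_curve(t), dtype=float)
    S = np.asarray(curves.S_curve(t), dtype=float)
    small = np.abs(L) < LOGNORMAL_L_THRESHOLD
    base = 1.0 + L * S * z
    if np.any(~small & (base <= 0)):
        raise ValueError("1 + L*S*z <= 0: latent deviate outside attainable range")
    Lsafe = np.where(small, 1.0, L)
    y = np.where(small, M * np.exp(S * z), M * np.power(np.where(small, 1.0, base), 1.0 / Lsafe))
    if y.ndim == 0:
        return float(y)
    return y


def _default_copula_correlation() -> pd.DataFrame:
    """Latent rank-correlation matrix of the six sampled parameters.

    Within-block correlations (FM-FM, LM-LM) are high, the FM-LM cross block
    is the conventional 0.3, and VAT tracks total adiposity.
    """
    params = list(SAMPLED_PARAMETERS)
    R = pd.DataFrame(np.eye(len(params)), index=params, columns=params)

    def set_(a, b, v):
        R.loc[a, b] = v
        R.loc[b, a] = v

    set_("fmi", "lmi", 0.3)
    set_("fmi", "appendicular_lmi", 0.3)
    set_("fmi", "fm_android_gynoid", 0.5)
    set_("fmi", "fm_trunk_limbs", 0.5)
    set_("fmi", "vat_mass", 0.7)
    set_("lmi", "appendicular_lmi", 0.85)
    set_("lmi", "fm_android_gynoid", 0.1)
    set_("lmi", "fm_trunk_limbs", 0.1)
    set_("lmi", "vat_mass", 0.3)
    set_("appendicular_lmi", "fm_android_gynoid", 0.1)
    set_("appendicular_lmi", "fm_trunk_limbs", 0.1)
    set_("appendicular_lmi", "vat_mass", 0.3)
    set_("fm_android_gynoid", "fm_trunk_limbs", 0.6)
    set_("fm_android_gynoid", "vat_mass", 0.5)
    set_("fm_trunk_limbs", "vat_mass", 0.5)
    return R


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort draw."""

    n_subjects: int = 10000
    sex_ratio: float = 5147 / 10894  # fraction male, as in the reference cohort
    age_distribution: str | dict[str, int] = "uniform"
    seed: int = 0
    copula_correlation: np.ndarray | None = None
    height_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (177.6, 7.1), "female": (164.3, 6.6)}
    )
    bmc_fraction: float = 0.04
    pregnancy_fraction: float = 0.005
    include_latents: bool = False

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 < self.bmc_fraction < 0.1:
            raise ValueError("bmc_fraction must lie in (0, 0.1)")
        if self.copula_correlation is None:
            self.copula_correlation = _default_copula_correlation().to_numpy()
        else:
            self.copula_correlation = np.asarray(self.copula_correlation, dtype=float)
        R = self.copula_correlation
        k = len(SAMPLED_PARAMETERS)
        if R.shape != (k, k) or not np.allclose(R, R.T):
            raise ValueError(f"copula_correlation must be a symmetric {k}x{k} matrix")
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            raise ValueError("copula_correlation is not positive semi-definite")
        if isinstance(self.age_distribution, dict):
            unknown = set(self.age_distribution) - set(table1.AGE_GROUP_LABELS)
            if unknown:
                raise ValueError(f"unknown age-group labels: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "sex_ratio": self.sex_ratio,
            "age_distribution": self.age_distribution,
            "seed": self.seed,
            "copula_correlation": np.asarray(self.copula_correlation).tolist(),
            "height_model": {k: list(v) for k, v in self.height_model.items()},
            "bmc_fraction": self.bmc_fraction,
            "pregnancy_fraction": self.pregnancy_fraction,
        }


def _sample_ages(config: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    a, b = AGE_DOMAIN
    if config.age_distribution == "uniform":
        return rng.uniform(a, b, size=n)
    counts = config.age_distribution
    ages = []
    for label, (lo, hi) in zip(table1.AGE_GROUP_LABELS, table1.AGE_GROUPS):
        c = int(counts.get(label, 0))
        ages.append(rng.uniform(lo, hi, size=c))
    ages = np.concatenate(ages) if ages else np.empty(0)
    if ages.size != n:
        raise ValueError(
            f"per-age-group counts sum to {ages.size}, expected n_subjects={n}"
        )
    return rng.permutation(ages)


def _head_fm_share(z_head: np.ndarray) -> np.ndarray:
    # small stochastic head/residual fat share in (0.02, 0.05)
    return 0.02 + 0.03 * expit(z_head)


def _gynoid_share(age: np.ndarray, sex_is_male: np.ndarray) -> np.ndarray:
    # gynoid-region share of total fat, declining gently with age
    frac = (age - AGE_DOMAIN[0]) / (AGE_DOMAIN[1] - AGE_DOMAIN[0])
    return np.where(sex_is_male, 0.18 - 0.02 * frac, 0.22 - 0.03 * frac)


def generate_cohort(
    config: CohortConfig,
    curve_library: dict[tuple[str, str], TrueCurveSet] | None = None,
):
    """Draw a synthetic cohort.

    Returns ``(cohort, curves)`` where ``cohort`` is a tidy DataFrame of
    per-subject records and ``curves`` is the generating curve library.
    Identical config (including seed) yields identical output.  Latent
    deviates that would leave the attainable Box-Cox range, or that would
    break the lean-mass additivity invariant, are resampled (truncated
    sampling; the rejected mass is negligible for the default curves).
    """
    if curve_library is None:
        curve_library = default_curve_library()
    for p in SAMPLED_PARAMETERS:
        for s in ("male", "female"):
            if (p, s) not in curve_library:
                raise ValueError(f"curve library missing ({p!r}, {s!r})")
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)

    sex_is_male = rng.random(n) < config.sex_ratio
    sex = np.where(sex_is_male, "male", "female")
    age = _sample_ages(config, rng, n)
    height = np.empty(n)
    for s in ("male", "female"):
        mask = sex == s
        mu, sd = config.height_model[s]
        height[mask] = rng.normal(mu, sd, size=int(mask.sum()))
    height = np.clip(height, 120.0, 220.0)

    R = np.asarray(config.copula_correlation)
    # eigenvalue factor tolerates semidefinite matrices
    evals, evecs = np.linalg.eigh(R)
    A = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    k = len(SAMPLED_PARAMETERS)
    latent = (A @ rng.standard_normal((k, n))).T
    z_head = rng.standard_normal(n)

    values = {p: np.empty(n) for p in SAMPLED_PARAMETERS}
    pending = np.ones(n, dtype=bool)
    h2 = (height / 100.0) ** 2
    for _round in range(200):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        ok = np.ones(idx.size, dtype=bool)
        for j, p in enumerate(SAMPLED_PARAMETERS):
            for s in ("male", "female"):
                mask = sex[idx] == s
                if not mask.any():
                    continue
                cs = curve_library[(p, s)]
                tt = age[idx][mask]
                zz = latent[idx, j][mask]
                L = np.asarray(cs.L_curve(tt), dtype=float)
                S = np.asarray(cs.S_curve(tt), dtype=float)
                bad = (np.abs(L) >= LOGNORMAL_L_THRESHOLD) & (1.0 + L * S * zz <= 0)
                sub_ok = ~bad
                vals = np.full(tt.shape, np.nan)
                if sub_ok.any():
                    vals[sub_ok] = sample_measurement(cs, tt[sub_ok], zz[sub_ok])
                values[p][idx[mask]] = vals
                sub = np.flatnonzero(mask)
                ok[sub[bad]] = False
        # lean additivity: limb lean cannot exceed total lean
        with np.errstate(invalid="ignore"):
            lean_bad = values["appendicular_lmi"][idx] > values["lmi"][idx]
        ok &= ~np.nan_to_num(lean_bad, nan=True).astype(bool)
        pending[idx[ok]] = False
        redraw = idx[~ok]
        if redraw.size:
            latent[redraw] = (A @ rng.standard_normal((k, redraw.size))).T
    else:
        raise RuntimeError("latent resampling failed to converge")

    fm_total = values["fmi"] * h2
    lm_total = values["lmi"] * h2
    lm_limbs = values["appendicular_lmi"] * h2
    tl = values["fm_trunk_limbs"]
    head_share = _head_fm_share(z_head)
    fm_limbs = (1.0 - head_share) * fm_total / (1.0 + tl)
    fm_trunk = (1.0 - head_share) * fm_total * tl / (1.0 + tl)
    fm_gynoid = _gynoid_share(age, sex_is_male) * fm_total
    fm_android = values["fm_android_gynoid"] * fm_gynoid
    vat_mass = values["vat_mass"]
    vat_volume = vat_mass / VAT_DENSITY_G_PER_CM3
    weight = (fm_total + lm_total) / (1.0 - config.bmc_fraction)
    pregnant = (~sex_is_male) & (rng.random(n) < config.pregnancy_fraction)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(1, n + 1)],
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "fm_total": fm_total,
            "fm_trunk": fm_trunk,
            "fm_limbs": fm_limbs,
            "fm_android": fm_android,
            "fm_gynoid": fm_gynoid,
            "lm_total": lm_total,
            "lm_limbs": lm_limbs,
            "vat_mass": vat_mass,
            "vat_volume": vat_volume,
            "pregnant_or_breastfeeding": pregnant,
        }
    )
    if config.include_latents:
        for j, p in enumerate(SAMPLED_PARAMETERS):
            cohort[f"z_{p}"] = latent[:, j]
    return cohort, curve_library
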