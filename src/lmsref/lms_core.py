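"""Box-Cox Cole-Green (LMS) reference-distribution engine.

The LMS method summarises how a positive measurement ``y`` (here a
body-composition index) varies with age ``t`` through three smooth curves:
the Box-Cox power ``L(t)`` that symmetrises the distribution, the median
``M(t)``, and the coefficient of variation ``S(t)``.  Conditional on age,

    z = ((y / M)**L - 1) / (L * S)          (L != 0)
    z = log(y / M) / S                      (L == 0, lognormal limit)

is standard normal, which yields centile curves by inverting the transform
at normal quantiles.

This module provides the BCCG density and z-transform, penalized
maximum-likelihood fitting of the three curves (cubic B-spline bases with a
second-order difference penalty, penalty strength solved so each curve's
effective degrees of freedom matches a requested target), BIC-based model
selection over a grid of degrees of freedom, and the pre-fit gross-outlier
screen based on standardized residuals of a linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "LOGNORMAL_L_THRESHOLD",
    "FitData",
    "CurveSpec",
    "LMSModel",
    "DomainError",
    "bccg_logdensity",
    "bccg_z",
    "bccg_inverse_z",
    "compute_z",
    "fit_lms",
    "select_model",
    "default_df_grid",
    "exclude_outliers",
]

#: below this |L| the Box-Cox transform switches to its lognormal limit
LOGNORMAL_L_THRESHOLD = 1e-5

_LOG_2PI = float(np.log(2.0 * np.pi))

# penalty strengths are re-solved for the first iterations while the working
# weights settle, then frozen so the penalized objective is well defined
_LAMBDA_FREEZE_ITER = 5


class DomainError(ValueError):
    """Raised when an age lies outside a model's fitted age domain."""


# ---------------------------------------------------------------------------
# distribution primitives


def _validate_lms_args(y, L, M, S):
    y, L, M, S = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (y, L, M, S)))
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("y must be finite and > 0")
    if np.any(M <= 0):
        raise ValueError("M must be > 0")
    if np.any(S <= 0):
        raise ValueError("S must be > 0")
    return y, L, M, S


def bccg_z(y, L, M, S):
    """Box-Cox z-transform: the standard-normal deviate of ``y`` under (L, M, S).

    Uses the lognormal limit when ``|L| < 1e-5``.
    """
    y, L, M, S = _validate_lms_args(y, L, M, S)
    ratio = y / M
    small = np.abs(L) < LOGNORMAL_L_THRESHOLD
    Lsafe = np.where(small, 1.0, L)
    with np.errstate(over="raise"):
        z = np.where(
            small,
            np.log(ratio) / S,
            (np.power(ratio, Lsafe) - 1.0) / (Lsafe * S),
        )
    if z.ndim == 0:
        return float(z)
    return z


def bccg_inverse_z(z, L, M, S):
    """Invert the z-transform: the measurement at standard-normal deviate ``z``.

    Requires ``1 + L*S*z > 0`` (the attainable region of the Box-Cox
    transform); raises ``ValueError`` outside it.
    """
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z must be finite")
    _, L, M, S = _validate_lms_args(1.0, L, M, S)
    z, L, M, S = np.broadcast_arrays(z, L, M, S)
    small = np.abs(L) < LOGNORMAL_L_THRESHOLD
    base = 1.0 + L * S * z
    if np.any(~small & (base <= 0.0)):
        raise ValueError(
            "1 + L*S*z <= 0: requested quantile outside the attainable range "
            "of the Box-Cox transform"
        )
    Lsafe = np.where(small, 1.0, L)
    y = np.where(small, M * np.exp(S * z), M * np.power(np.where(small, 1.0, base), 1.0 / Lsafe))
    if y.ndim == 0:
        return float(y)
    return y


def bccg_logdensity(y, L, M, S, truncated: bool = False):
    """Log-density of the Box-Cox Cole-Green distribution.

    ``log f(y) = (L-1)*log(y/M) - log(M*S) - z^2/2 - log(2*pi)/2``.

    By default the truncation constant for the ``y > 0`` support (the
    ``z > -1/(L*S)`` boundary) is ignored, as in classical LMS fitting where
    the truncated mass is negligible; ``truncated=True`` applies the exact
    normalization ``Phi(1/(|L|*S))``.
    """
    y, L, M, S = _validate_lms_args(y, L, M, S)
    z = np.asarray(bccg_z(y, L, M, S))
    logf = (L - 1.0) * np.log(y / M) - np.log(M * S) - 0.5 * z**2 - 0.5 * _LOG_2PI
    if truncated:
        big = np.abs(L) >= LOGNORMAL_L_THRESHOLD
        norm_const = np.where(big, stats.norm.cdf(1.0 / (np.abs(L) * S)), 1.0)
        logf = logf - np.log(norm_const)
    if logf.ndim == 0:
        return float(logf)
    return logf


# ---------------------------------------------------------------------------
# data container


@dataclass
class FitData:
    """Age/measurement pairs (and optional prior weights) for one parameter."""

    t: np.ndarray
    y: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-d arrays of equal length")
        if np.any(~np.isfinite(self.t)) or np.any(~np.isfinite(self.y)):
            raise ValueError("t and y must be finite")
        if np.any(self.y <= 0):
            raise ValueError("y must be positive")
        if self.weights is None:
            self.weights = np.ones_like(self.y)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.y.shape or np.any(self.weights < 0):
                raise ValueError("weights must be non-negative, same length as y")

    def __len__(self) -> int:
        return self.t.size


def _as_fitdata(data) -> FitData:
    if isinstance(data, FitData):
        return data
    if isinstance(data, (tuple, list)) and len(data) == 2:
        return FitData(np.asarray(data[0]), np.asarray(data[1]))
    raise TypeError("data must be a FitData or a (t, y) pair")


# ---------------------------------------------------------------------------
# curve bases


@dataclass(frozen=True)
class CurveSpec:
    """One fitted smooth curve: basis description plus coefficients.

    ``kind`` is ``constant`` (df 0), ``linear`` (df 1) or ``bspline``
    (df >= 2: cubic B-splines, second-order difference penalty with strength
    ``lam`` chosen so the effective degrees of freedom equal ``df + 1``
    including the intercept).
    """

    kind: str
    df: int
    domain: tuple[float, float]
    coef: tuple[float, ...]
    knots: tuple[float, ...] = ()
    lam: float = 0.0

    def design(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a, b = self.domain
        if self.kind == "constant":
            return np.ones((t.size, 1))
        if self.kind == "linear":
            # scaled age keeps the linear basis well conditioned
            x = (t - 0.5 * (a + b)) / (0.5 * (b - a))
            return np.column_stack([np.ones(t.size), x])
        if self.kind == "bspline":
            tt = np.asarray(self.knots)
            x = np.clip(t, tt[3], tt[-4])
            return BSpline.design_matrix(x, tt, 3).toarray()
        raise ValueError(f"unknown curve kind {self.kind!r}")

    def penalty(self) -> np.ndarray:
        p = len(self.coef)
        if self.kind != "bspline":
            return np.zeros((p, p))
        d2 = np.diff(np.eye(p), n=2, axis=0)
        return d2.T @ d2

    def __call__(self, t) -> np.ndarray:
        return self.design(np.atleast_1d(t)) @ np.asarray(self.coef)


def _make_curvespec(df: int, domain: tuple[float, float]) -> CurveSpec:
    a, b = domain
    if df < 0:
        raise ValueError("df must be >= 0")
    if df == 0:
        return CurveSpec("constant", 0, domain, (0.0,))
    if df == 1:
        return CurveSpec("linear", 1, domain, (0.0, 0.0))
    nbasis = df + 4  # leaves room for the penalty to shrink edf to df+1
    interior = np.linspace(a, b, nbasis - 2)[1:-1]
    knots = np.r_[[a] * 4, interior, [b] * 4]
    return CurveSpec("bspline", df, domain, (0.0,) * nbasis, tuple(knots))


def _constant_coef(spec: CurveSpec, value: float) -> np.ndarray:
    """Coefficient vector representing the constant curve ``value``."""
    p = len(spec.coef)
    if spec.kind == "linear":
        return np.array([value, 0.0])
    # constant basis, and B-splines by partition of unity
    return np.full(p, value)


def _solve_lambda(BtWB: np.ndarray, P: np.ndarray, target_edf: float) -> float:
    """Penalty strength such that trace of the smoother equals target_edf."""

    def edf(lam: float) -> float:
        return float(np.trace(np.linalg.solve(BtWB + lam * P, BtWB)))

    scale = np.trace(BtWB) / max(np.trace(P), 1e-12)
    lo, hi = scale * 1e-9, scale * 1e12
    if edf(lo) <= target_edf:
        return lo
    if edf(hi) >= target_edf:
        return hi

    def g(loglam: float) -> float:
        return edf(10.0**loglam) - target_edf

    loglam = optimize.brentq(g, np.log10(lo), np.log10(hi), xtol=1e-8)
    return float(10.0**loglam)


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class LMSModel:
    """Fitted smooth L(t), M(t), S(t) curves for one parameter/sex/stratum.

    M and S are parameterised on the log scale (guaranteeing positivity);
    ``L_spec``, ``M_spec``, ``S_spec`` store the spline bases and
    coefficients. The age domain is half-open ``[t_min, t_max)`` and the model
    refuses to extrapolate outside it.
    """

    parameter_name: str
    sex: str
    stratum: str
    L_spec: CurveSpec
    M_spec: CurveSpec
    S_spec: CurveSpec
    df: tuple[int, int, int]
    domain: tuple[float, float]
    n_fit: int
    log_likelihood: float
    bic: float
    converged: bool
    iterations: int
    penalized_ll_trace: list[float] = field(default_factory=list)

    def _check_domain(self, t: np.ndarray) -> None:
        a, b = self.domain
        if np.any(t < a) or np.any(t >= b):
            raise DomainError(
                f"age outside model domain [{a}, {b}): no extrapolation"
            )

    def _curves_at(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t)
        L = self.L_spec(t)
        M = np.exp(self.M_spec(t))
        S = np.exp(self.S_spec(t))
        return L, M, S

    def L(self, t):
        return self._scalarize(self._curves_at(t)[0], t)

    def M(self, t):
        return self._scalarize(self._curves_at(t)[1], t)

    def S(self, t):
        return self._scalarize(self._curves_at(t)[2], t)

    @staticmethod
    def _scalarize(values: np.ndarray, t) -> float | np.ndarray:
        return float(values[0]) if np.ndim(t) == 0 else values

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def spec_dict(s: CurveSpec) -> dict:
            return {
                "kind": s.kind,
                "df": s.df,
                "domain": [float(x) for x in s.domain],
                "coef": [float(c) for c in s.coef],
                "knots": [float(k) for k in s.knots],
                "lam": float(s.lam),
            }

        return {
            "parameter_name": self.parameter_name,
            "sex": self.sex,
            "stratum": self.stratum,
            "curves": {
                "L": spec_dict(self.L_spec),
                "M": spec_dict(self.M_spec),
                "S": spec_dict(self.S_spec),
            },
            "df": list(self.df),
            "domain": [float(x) for x in self.domain],
            "n_fit": int(self.n_fit),
            "log_likelihood": float(self.log_likelihood),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMSModel":
        def spec(s: dict) -> CurveSpec:
            return CurveSpec(
                s["kind"],
                int(s["df"]),
                tuple(s["domain"]),
                tuple(s["coef"]),
                tuple(s["knots"]),
                float(s["lam"]),
            )

        return cls(
            parameter_name=d["parameter_name"],
            sex=d["sex"],
            stratum=d["stratum"],
            L_spec=spec(d["curves"]["L"]),
            M_spec=spec(d["curves"]["M"]),
            S_spec=spec(d["curves"]["S"]),
            df=tuple(d["df"]),
            domain=tuple(d["domain"]),
            n_fit=int(d["n_fit"]),
            log_likelihood=float(d["log_likelihood"]),
            bic=float(d["bic"]),
            converged=bool(d["converged"]),
            iterations=int(d["iterations"]),
        )


def compute_z(y, t, model: LMSModel):
    """z-scores of measurements ``y`` at ages ``t`` under a fitted model."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    L, M, S = model._curves_at(t_arr)
    z = np.asarray(bccg_z(np.atleast_1d(y), L, M, S))
    return float(z[0]) if np.ndim(y) == 0 and np.ndim(t) == 0 else z


# ---------------------------------------------------------------------------
# penalized likelihood fitting


def _loglik_terms(y, L, M, S, w):
    z = np.asarray(bccg_z(y, L, M, S))
    ll = w * ((L - 1.0) * np.log(y / M) - np.log(M * S) - 0.5 * z**2 - 0.5 * _LOG_2PI)
    return float(np.sum(ll)), z


def _penalized_ll(y, w, specs, coefs, lams, designs):
    L = designs["L"] @ coefs["L"]
    etaM = designs["M"] @ coefs["M"]
    etaS = designs["S"] @ coefs["S"]
    if np.max(np.abs(L)) > 8 or np.max(np.abs(etaS)) > 20 or np.max(np.abs(etaM)) > 50:
        return -np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        try:
            ll, _ = _loglik_terms(y, L, np.exp(etaM), np.exp(etaS), w)
        except (FloatingPointError, ValueError):
            return -np.inf
    if not np.isfinite(ll):
        return -np.inf
    pen = 0.0
    for name in ("L", "M", "S"):
        P = specs[name].penalty()
        c = coefs[name]
        pen += 0.5 * lams[name] * float(c @ P @ c)
    return ll - pen


def _scores_and_weights(name, y, L, M, S, z):
    """Per-observation score and expected information on the working scale.

    M and S enter through their logs; L is fitted on its own scale.  The
    expected-information weights are the classical Cole-Green ones.
    """
    u = (y / M) ** np.where(np.abs(L) < LOGNORMAL_L_THRESHOLD, 0.0, L)
    u = np.where(np.abs(L) < LOGNORMAL_L_THRESHOLD, 1.0 + L * S * z, u)
    nu = np.log(y / M)
    if name == "M":
        score = -L + z * u / S
        info = (1.0 + 2.0 * L**2 * S**2) / S**2
    elif name == "S":
        score = z**2 - 1.0
        info = np.full_like(z, 2.0)
    else:  # L
        small = np.abs(L) < LOGNORMAL_L_THRESHOLD
        with np.errstate(invalid="ignore", divide="ignore"):
            dz_dL = np.where(
                small,
                nu**2 / (2.0 * S),
                u * nu / (L * S) - z / L,
            )
        score = nu - z * dz_dL
        info = np.maximum(7.0 * S**2 / 4.0, 1e-8)
    return score, info


def fit_lms(
    data,
    df: tuple[int, int, int] = (0, 2, 1),
    *,
    domain: tuple[float, float] | None = None,
    parameter_name: str = "",
    sex: str = "",
    stratum: str = "all",
    max_iter: int = 200,
    tol: float = 1e-6,
    fix_L: float | None = None,
) -> LMSModel:
    """Fit smooth L/M/S curves by penalized maximum likelihood.

    ``df = (df_L, df_M, df_S)`` are the requested effective degrees of
    freedom beyond the intercept for each curve; 0 means constant, 1 linear,
    >= 2 a penalized cubic B-spline whose smoothing strength is solved so the
    trace of the smoother equals ``df + 1``.  Fitting is Fisher-scoring
    backfitting across the three curves with step-halving, which makes the
    penalized log-likelihood non-decreasing once the penalties are frozen.

    ``fix_L`` holds the Box-Cox power constant at the given value instead of
    estimating it (``fix_L=1`` reduces the model to additive normal errors
    with SD proportional to M; ``fix_L=0`` to a lognormal model).
    """
    data = _as_fitdata(data)
    df = tuple(int(d) for d in df)
    if len(df) != 3 or any(d < 0 for d in df):
        raise ValueError("df must be three non-negative integers")
    n = len(data)
    if n < 50:
        raise ValueError("need at least 50 observations to fit an LMS model")
    t, y, w = data.t, data.y, data.weights
    if np.allclose(y, y[0]):
        raise ValueError("all y identical: scale is not estimable")
    if domain is None:
        a = float(np.min(t))
        b = float(np.nextafter(np.max(t), np.inf))
        domain = (a, b)
    else:
        domain = (float(domain[0]), float(domain[1]))
        if np.any(t < domain[0]) or np.any(t >= domain[1]):
            raise DomainError("fit data outside the requested age domain")

    specs = {
        "L": _make_curvespec(df[0], domain),
        "M": _make_curvespec(df[1], domain),
        "S": _make_curvespec(df[2], domain),
    }
    designs = {name: specs[name].design(t) for name in specs}
    penalties = {name: specs[name].penalty() for name in specs}
    targets = {"L": df[0] + 1.0, "M": df[1] + 1.0, "S": df[2] + 1.0}

    # --- initialization: L = 1, M = smooth of log y, S = residual CV
    lny = np.log(y)
    coefs: dict[str, np.ndarray] = {}
    lams = {"L": 0.0, "M": 0.0, "S": 0.0}
    B = designs["M"]
    BtWB = B.T @ (w[:, None] * B)
    if specs["M"].kind == "bspline":
        lams["M"] = _solve_lambda(BtWB, penalties["M"], targets["M"])
    coefs["M"] = np.linalg.solve(
        BtWB + lams["M"] * penalties["M"], B.T @ (w * lny)
    )
    resid = lny - B @ coefs["M"]
    s0 = float(np.clip(np.std(resid), 1e-3, 2.0))
    coefs["S"] = _constant_coef(specs["S"], np.log(s0))
    coefs["L"] = _constant_coef(specs["L"], 1.0 if fix_L is None else float(fix_L))
    curve_order = ("M", "S") if fix_L is not None else ("M", "S", "L")

    def current_pll() -> float:
        return _penalized_ll(y, w, specs, coefs, lams, designs)

    pll = current_pll()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for name in curve_order:
            Lc = designs["L"] @ coefs["L"]
            Mc = np.exp(designs["M"] @ coefs["M"])
            Sc = np.exp(designs["S"] @ coefs["S"])
            z = np.asarray(bccg_z(y, Lc, Mc, Sc))
            score, info = _scores_and_weights(name, y, Lc, Mc, Sc, z)
            ww = w * info
            Bc = designs[name]
            BtWBc = Bc.T @ (ww[:, None] * Bc)
            if specs[name].kind == "bspline" and it <= _LAMBDA_FREEZE_ITER:
                lams[name] = _solve_lambda(BtWBc, penalties[name], targets[name])
            eta = Bc @ coefs[name]
            zeta = eta + score / info
            new_coef = np.linalg.solve(
                BtWBc + lams[name] * penalties[name], Bc.T @ (ww * zeta)
            )
            old_coef = coefs[name]
            coefs[name] = new_coef
            # step-halving keeps the penalized objective non-decreasing
            for _ in range(30):
                if current_pll() >= pll - 1e-10:
                    break
                coefs[name] = 0.5 * (coefs[name] + old_coef)
            else:
                coefs[name] = old_coef
            pll = current_pll()
        if it > _LAMBDA_FREEZE_ITER:
            trace.append(pll)
            if len(trace) >= 2:
                prev = trace[-2]
                if abs(pll - prev) <= tol * (abs(prev) + 1e-8):
                    converged = True
                    break

    if not converged:
        warnings.warn(
            f"LMS fit did not converge in {max_iter} iterations "
            f"(df={df}, parameter={parameter_name!r})",
            RuntimeWarning,
        )

    Lc = designs["L"] @ coefs["L"]
    Mc = np.exp(designs["M"] @ coefs["M"])
    Sc = np.exp(designs["S"] @ coefs["S"])
    ll, _ = _loglik_terms(y, Lc, Mc, Sc, w)
    k = sum(df) + 3
    bic = -2.0 * ll + k * np.log(n)

    def finalize(name: str) -> CurveSpec:
        return replace(specs[name], coef=tuple(float(c) for c in coefs[name]), lam=lams[name])

    return LMSModel(
        parameter_name=parameter_name,
        sex=sex,
        stratum=stratum,
        L_spec=finalize("L"),
        M_spec=finalize("M"),
        S_spec=finalize("S"),
        df=df,
        domain=domain,
        n_fit=n,
        log_likelihood=ll,
        bic=float(bic),
        converged=converged,
        iterations=it,
        penalized_ll_trace=trace,
    )


def default_df_grid() -> list[tuple[int, int, int]]:
    """Default search grid: df_L in {0,1,2}, df_M in {1..6}, df_S in {0..3}."""
    return [
        (dl, dm, ds)
        for dl in (0, 1, 2)
        for dm in (1, 2, 3, 4, 5, 6)
        for ds in (0, 1, 2, 3)
    ]


def select_model(data, df_grid=None, **fit_kwargs) -> LMSModel:
    """Fit every df combination in the grid and return the minimum-BIC model.

    Ties (within 1e-8 relative BIC) break toward the smallest total df, then
    lexicographically on (df_M, df_S, df_L).  Only converged fits compete.
    """
    data = _as_fitdata(data)
    grid = [tuple(int(x) for x in d) for d in (df_grid if df_grid is not None else default_df_grid())]
    if not grid:
        raise ValueError("df_grid must be non-empty")
    models = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for df in grid:
            try:
                models.append(fit_lms(data, df, **fit_kwargs))
            except (ValueError, np.linalg.LinAlgError):
                continue
    converged = [m for m in models if m.converged]
    if not converged:
        raise RuntimeError("no df combination converged")
    bic0 = min(m.bic for m in converged)
    tol = 1e-8 * (abs(bic0) + 1.0)

    def key(m: LMSModel):
        quantized = 0.0 if abs(m.bic - bic0) <= tol else m.bic - bic0
        return (quantized, sum(m.df), (m.df[1], m.df[2], m.df[0]))

    return min(converged, key=key)


# ---------------------------------------------------------------------------
# outlier screen


def exclude_outliers(data, threshold: float = 10.0):
    """Drop gross outliers before LMS fitting.

    An ordinary least-squares line of ``y`` on ``t`` is fitted; observations
    whose standardized residual exceeds ``threshold`` in absolute value are
    removed in a single pass.  Returns ``(kept FitData, removed indices)``.
    """
    data = _as_fitdata(data)
    n = len(data)
    if n < 10:
        raise ValueError("need at least 10 observations for the outlier screen")
    t, y = data.t, data.y
    if np.allclose(t, t[0]):
        raise ValueError("degenerate design: all ages identical")
    X = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = float(np.std(resid, ddof=2))
    if sd == 0.0:
        mask = np.zeros(n, dtype=bool)
    else:
        mask = np.abs(resid / sd) > threshold
    kept = FitData(t[~mask], y[~mask], data.weights[~mask])
    removed = np.flatnonzero(mask)
    return kept, removed
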