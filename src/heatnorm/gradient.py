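"""Gradient-dependent genetic parameters from reaction-norm components.

With a 2×2 covariance function K = [[v_int, c_is], [c_is, v_slope]] for a
random intercept+slope pair, the variance contributed at gradient value x is
the quadratic form w'Kw with w = (1, x):

    Var(x) = v_int + 2x·c_is + x²·v_slope,

and the correlation between the effect expressed at x1 and at x2 is

    r(x1, x2) = (v_int + (x1+x2)·c_is + x1·x2·v_slope) / sqrt(Var(x1)·Var(x2)).

Heritabilities use the phenotypic variance
v_p(x) = v_d + Var_m(x) + Var_pe(x) + v_hym + v_e; the herd-year-month
variance is included in the denominator by default (it is a random model
term) and can be excluded with ``include_hym=False``.

Approximate standard errors propagate the asymptotic covariance of the REML
variance parameters (inverse average-information matrix) through these
functions by the delta method with central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CovarianceFunction2x2",
    "Model2Components",
    "variance_at",
    "correlation_between_envs",
    "heritabilities_at",
    "gradient_table",
    "parameter_ses",
    "DEFAULT_GRID",
]

DEFAULT_GRID = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class CovarianceFunction2x2:
    """Intercept/slope (co)variances of one reaction-norm term.

    Units: v_int kg², v_slope kg² per scaled-unit², c_is kg² per scaled unit.
    """

    v_int: float
    c_is: float
    v_slope: float

    def __post_init__(self):
        if self.v_int < 0 or self.v_slope < 0:
            raise ValueError("intercept/slope variances must be non-negative")
        if self.c_is**2 > self.v_int * self.v_slope * (1 + 1e-10) + 1e-12:
            raise ValueError("covariance function is not positive semi-definite")

    @classmethod
    def from_matrix(cls, K) -> "CovarianceFunction2x2":
        K = np.asarray(K, dtype=float)
        return cls(float(K[0, 0]), float(K[0, 1]), float(K[1, 1]))

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.v_int, self.c_is], [self.c_is, self.v_slope]])


def _as_cf(K) -> CovarianceFunction2x2:
    return K if isinstance(K, CovarianceFunction2x2) else CovarianceFunction2x2.from_matrix(K)


def variance_at(K, x):
    """Variance of the reaction-norm effect at gradient value x (w'Kw)."""
    cf = _as_cf(K)
    x = np.asarray(x, dtype=float)
    v = cf.v_int + 2.0 * x * cf.c_is + x**2 * cf.v_slope
    return v if v.ndim else float(v)


def correlation_between_envs(K, x1, x2):
    """Correlation of the same effect expressed at gradient values x1 and x2."""
    cf = _as_cf(K)
    v1, v2 = variance_at(cf, x1), variance_at(cf, x2)
    if np.any(np.asarray(v1) <= 0) or np.any(np.asarray(v2) <= 0):
        raise ValueError("zero variance at a gradient point: correlation undefined")
    cov = cf.v_int + (np.asarray(x1, dtype=float) + np.asarray(x2, dtype=float)) * cf.c_is \
        + np.asarray(x1, dtype=float) * np.asarray(x2, dtype=float) * cf.v_slope
    r = cov / np.sqrt(v1 * v2)
    return r if np.ndim(r) else float(r)


@dataclass(frozen=True)
class Model2Components:
    """Variance components of the maternal reaction-norm model (kg² scale)."""

    v_d: float
    K_m: CovarianceFunction2x2
    K_pe: CovarianceFunction2x2
    v_hym: float
    v_e: float

    @classmethod
    def from_fit(cls, model) -> "Model2Components":
        """Build from a fitted :class:`~heatnorm.models.MaternalReactionNormModel`."""
        return cls(
            v_d=model.v_d_,
            K_m=CovarianceFunction2x2.from_matrix(model.K_m_),
            K_pe=CovarianceFunction2x2.from_matrix(model.K_pe_),
            v_hym=model.v_hym_,
            v_e=model.v_e_,
        )


def heritabilities_at(components: Model2Components, x, include_hym: bool = True):
    """Direct/maternal heritability and pe proportion at gradient value x.

    Returns a dict with v_m, v_pe, v_p, h2_d, h2_m, pe_proportion.
    """
    c = components
    v_m = variance_at(c.K_m, x)
    v_pe = variance_at(c.K_pe, x)
    v_p = c.v_d + v_m + v_pe + c.v_e + (c.v_hym if include_hym else 0.0)
    if np.any(np.asarray(v_p) <= 0):
        raise ValueError("non-positive phenotypic variance")
    return {
        "v_m": v_m,
        "v_pe": v_pe,
        "v_p": v_p,
        "h2_d": c.v_d / v_p,
        "h2_m": v_m / v_p,
        "pe_proportion": v_pe / v_p,
    }


def gradient_table(components: Model2Components, grid=DEFAULT_GRID,
                   include_hym: bool = True) -> pd.DataFrame:
    """Tidy per-gradient-point parameter table, plus correlations with x=1."""
    grid = np.asarray(grid, dtype=float)
    rows = []
    for x in grid:
        h = heritabilities_at(components, x, include_hym=include_hym)
        rows.append(
            {
                "x": x,
                **{k: float(v) for k, v in h.items()},
                "r_mg_max": correlation_between_envs(components.K_m, 1.0, x),
                "r_mpe_max": correlation_between_envs(components.K_pe, 1.0, x),
            }
        )
    return pd.DataFrame(rows)


_PARAM_ORDER = ["v_d", "m_v_int", "m_c_is", "m_v_slope",
                "pe_v_int", "pe_c_is", "pe_v_slope", "v_hym", "v_e"]


def _components_from_theta(theta) -> Model2Components:
    t = dict(zip(_PARAM_ORDER, theta))
    # bypass the PSD validation: finite-difference perturbations may leave the cone
    km = CovarianceFunction2x2.__new__(CovarianceFunction2x2)
    object.__setattr__(km, "v_int", t["m_v_int"])
    object.__setattr__(km, "c_is", t["m_c_is"])
    object.__setattr__(km, "v_slope", t["m_v_slope"])
    kpe = CovarianceFunction2x2.__new__(CovarianceFunction2x2)
    object.__setattr__(kpe, "v_int", t["pe_v_int"])
    object.__setattr__(kpe, "c_is", t["pe_c_is"])
    object.__setattr__(kpe, "v_slope", t["pe_v_slope"])
    return Model2Components(t["v_d"], km, kpe, t["v_hym"], t["v_e"])


def parameter_ses(result, grid=DEFAULT_GRID, include_hym: bool = True) -> pd.DataFrame:
    """Delta-method SEs of the gradient parameters from a model-2 REML result.

    ``result`` is the :class:`~heatnorm.reml.REMLResult` of a maternal
    reaction-norm fit (parameter order v_d, K_m, K_pe, v_hym, v_e).  The
    component covariance is the inverse average-information matrix; the
    Jacobian uses central differences.  Returns one row per grid point with
    SEs for v_m, h2_d, h2_m, pe_proportion, r_mg(1,x) and r_mpe(1,x).
    """
    if list(result.param_names) != _PARAM_ORDER:
        raise ValueError(f"unexpected parameter order {result.param_names}")
    theta = np.asarray(result.theta, dtype=float)
    sigma = result.ai_inv
    if not np.all(np.isfinite(sigma)):
        raise np.linalg.LinAlgError("singular AI matrix: SEs unavailable")
    grid = np.asarray(grid, dtype=float)
    out_names = ["v_m", "h2_d", "h2_m", "pe_proportion", "r_mg_max", "r_mpe_max"]

    def func(th):
        c = _components_from_theta(th)
        vals = []
        for x in grid:
            h = heritabilities_at(c, x, include_hym=include_hym)
            vals.append(
                [h["v_m"], h["h2_d"], h["h2_m"], h["pe_proportion"],
                 correlation_between_envs(c.K_m, 1.0, x),
                 correlation_between_envs(c.K_pe, 1.0, x)]
            )
        return np.asarray(vals)  # (len(grid), 6)

    J = np.zeros((len(grid), len(out_names), len(theta)))
    for k in range(len(theta)):
        h = 1e-5 * max(abs(theta[k]), 1e-3)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, :, k] = (func(tp) - func(tm)) / (2.0 * h)
    var = np.einsum("gik,kl,gil->gi", J, sigma, J)
    se = np.sqrt(np.clip(var, 0.0, None))
    df = pd.DataFrame(se, columns=[f"se_{n}" for n in out_names])
    df.insert(0, "x", grid)
    return df
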