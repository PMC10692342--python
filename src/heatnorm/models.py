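"""The two birth-weight mixed models as sklearn-style estimators.

Model 1 (fixed heat-load regression):

    y = Xb + Ks + Mh + Q c_hym + e

with i.i.d. random sire (s), dam (h) and herd-year-month (c_hym) effects.
The fixed part b holds the overall mean, herd-birth-year, sex × birth type,
gestation-length class, dam-parity class and one linear regression on a
scaled heat-load covariate; the model is run once per covariate
(s_wk1..s_wk12, s_pc1).

Model 2 (maternal reaction norm):

    y = Xb + Zd + Wm + Sp_m + Q c_hym + e

with a direct additive genetic effect d (relationship-structured, intercept
only), maternal genetic intercept+slope pairs m on the scaled gradient
(relationship-structured, covariance function K_m), maternal
permanent-environmental intercept+slope pairs p_m (i.i.d. across dams,
covariance function K_pe) and random herd-year-month.  The relationship
matrix may be the pedigree A or the single-step H.

Both estimators expect a record table that already carries the model factors
(see :func:`heatnorm.editing.assign_classes`) and the scaled covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator

from .reml import RandomRegressionTerm, ScalarTerm, reml_fit

__all__ = [
    "FIXED_FACTORS",
    "fixed_design",
    "build_design",
    "FixedRegressionModel",
    "MaternalReactionNormModel",
    "run_model1_battery",
    "ALL_COVARIATES",
]

FIXED_FACTORS = ["hy", "sex_bt", "gl_class", "parity_class"]
ALL_COVARIATES = [f"s_wk{k}" for k in range(1, 13)] + ["s_pc1"]


def fixed_design(records: pd.DataFrame, covariate: str):
    """Full-rank dense fixed-effect design: intercept, covariate, then
    drop-first dummies for each factor.  Returns (X, column names)."""
    for col in FIXED_FACTORS + [covariate]:
        if col not in records:
            raise ValueError(f"records lack required column {col!r}")
    cols = [np.ones(len(records)), records[covariate].to_numpy(dtype=float)]
    names = ["intercept", covariate]
    for f in FIXED_FACTORS:
        d = pd.get_dummies(records[f].astype(str), prefix=f, drop_first=True)
        cols.extend(d[c].to_numpy(dtype=float) for c in d.columns)
        names.extend(d.columns)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X, names = _drop_collinear(X, names, protected=2)
    return X, names


def _drop_collinear(X, names, protected):
    """Drop dependent dummy columns (QR with pivoting); the first ``protected``
    columns (intercept, covariate) must stay estimable."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    rank = int((diag > tol).sum())
    drop = set(piv[rank:])
    if any(j < protected for j in drop):
        raise ValueError("covariate column is collinear with the factor structure")
    keep = [j for j in range(X.shape[1]) if j not in drop]
    return X[:, keep], [names[j] for j in keep]


def _indicator(groups) -> tuple[sp.csr_matrix, np.ndarray]:
    levels, codes = np.unique(np.asarray(groups), return_inverse=True)
    n = len(codes)
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, len(levels)))
    return Z, levels


def build_design(records: pd.DataFrame, covariate: str, model: int = 2) -> dict:
    """Sparse design matrices of the requested model.

    Model 1 returns X, K (sire), M (dam), Q (hym); model 2 returns X,
    Z (calf), W and S (two columns per dam: intercept and the calf's scaled
    covariate as slope regressor) and Q (hym).
    """
    Xd, names = fixed_design(records, covariate)
    X = sp.csr_matrix(Xd)
    Q, hym_levels = _indicator(records["hym"])
    out = {"X": X, "x_names": names, "Q": Q, "hym_levels": hym_levels}
    if model == 1:
        out["K"], out["sire_levels"] = _indicator(records["sire_id"])
        out["M"], out["dam_levels"] = _indicator(records["dam_id"])
    elif model == 2:
        out["Z"], out["calf_levels"] = _indicator(records["calf_id"])
        Wi, dam_levels = _indicator(records["dam_id"])
        x = sp.diags(records[covariate].to_numpy(dtype=float))
        interleave = sp.hstack([Wi, x @ Wi]).tocsr()
        out["W"] = interleave
        out["S"] = interleave.copy()
        out["dam_levels"] = dam_levels
    else:
        raise ValueError("model must be 1 or 2")
    return out


def _subset_relationship(groups, rel: np.ndarray, rel_ids) -> np.ndarray:
    """Relationship block for the unique group levels, in np.unique order."""
    pos = {v: i for i, v in enumerate(rel_ids)}
    levels = np.unique(np.asarray(groups))
    missing = [v for v in levels if v not in pos]
    if missing:
        raise ValueError(f"ids missing from relationship matrix: {missing[:5]}")
    idx = np.array([pos[v] for v in levels])
    return np.asarray(rel, dtype=float)[np.ix_(idx, idx)]


def _wald(beta, beta_cov, names, covariate):
    j = names.index(covariate)
    se = float(np.sqrt(beta_cov[j, j]))
    z = beta[j] / se if se > 0 else np.inf
    return float(beta[j]), se, float(2.0 * stats.norm.sf(abs(z)))


class FixedRegressionModel(BaseEstimator):
    """Model 1: fixed heat-load regression with i.i.d. sire/dam/HYM effects.

    Parameters
    ----------
    covariate : which scaled heat-load column to regress on.
    max_iter, tol_param, tol_logl : AI-REML controls.

    Fitted attributes: ``coef_`` (kg per scaled unit), ``coef_se_``,
    ``p_value_`` (Wald), ``varcomp_`` (v_sire, v_dam, v_hym, v_e),
    ``loglik_``, ``beta_``, ``x_names_``, ``result_``.
    """

    def __init__(self, covariate: str = "s_pc1", max_iter: int = 200,
                 tol_param: float = 1e-8, tol_logl: float = 1e-6, start=None):
        self.covariate = covariate
        self.max_iter = max_iter
        self.tol_param = tol_param
        self.tol_logl = tol_logl
        self.start = start

    def fit(self, data: pd.DataFrame, y=None):
        df = data.reset_index(drop=True)
        yy = df["biw_kg"].to_numpy(dtype=float) if y is None else np.asarray(y, dtype=float)
        X, names = fixed_design(df, self.covariate)
        terms = [
            ScalarTerm("sire", df["sire_id"].to_numpy()),
            ScalarTerm("dam", df["dam_id"].to_numpy()),
            ScalarTerm("hym", df["hym"].to_numpy()),
        ]
        res = reml_fit(X, yy, terms, start=self.start, max_iter=self.max_iter,
                       tol_param=self.tol_param, tol_logl=self.tol_logl)
        self.result_ = res
        self.x_names_ = names
        self.beta_ = res.beta
        self.coef_, self.coef_se_, self.p_value_ = _wald(res.beta, res.beta_cov, names, self.covariate)
        self.varcomp_ = dict(zip(res.param_names, res.theta))
        self.loglik_ = res.loglik
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fixed-part prediction (no random effects)."""
        X, names = fixed_design(data.reset_index(drop=True), self.covariate)
        if names != self.x_names_:
            raise ValueError("factor levels differ from the fitted design")
        return X @ self.beta_


class MaternalReactionNormModel(BaseEstimator):
    """Model 2: direct additive + maternal genetic/permanent-environmental
    reaction norms on a scaled heat-load gradient.

    Parameters
    ----------
    covariate : scaled gradient column (default s_pc1).
    relationship : dense relationship matrix (A or single-step H) over
        ``relationship_ids``; used for the direct effect (calves) and the
        maternal genetic pairs (dams).  ``None`` fits i.i.d. genetic effects.
    relationship_ids : ids indexing ``relationship``.
    direct_maternal_cov : fixed at zero (no d–m covariance term); kept as a
        constructor flag for API stability.

    Fitted attributes: ``v_d_``, ``K_m_`` and ``K_pe_`` (2×2 arrays, order
    [intercept, slope]), ``v_hym_``, ``v_e_``, ``coef_``/``coef_se_``/
    ``p_value_`` for the fixed heat-load regression, ``loglik_``,
    ``result_``.
    """

    def __init__(self, covariate: str = "s_pc1", relationship=None,
                 relationship_ids=None, direct_maternal_cov: bool = False,
                 max_iter: int = 200, tol_param: float = 1e-8,
                 tol_logl: float = 1e-6, start=None):
        self.covariate = covariate
        self.relationship = relationship
        self.relationship_ids = relationship_ids
        self.direct_maternal_cov = direct_maternal_cov
        self.max_iter = max_iter
        self.tol_param = tol_param
        self.tol_logl = tol_logl
        self.start = start

    def _terms(self, df: pd.DataFrame):
        x = df[self.covariate].to_numpy(dtype=float)
        calf = df["calf_id"].to_numpy()
        dam = df["dam_id"].to_numpy()
        if self.relationship is not None:
            if self.relationship_ids is None:
                raise ValueError("relationship_ids required with a relationship matrix")
            rel_c = _subset_relationship(calf, self.relationship, self.relationship_ids)
            rel_d = _subset_relationship(dam, self.relationship, self.relationship_ids)
        else:
            rel_c = rel_d = None
        if self.direct_maternal_cov:
            raise NotImplementedError("direct–maternal covariance is fixed at zero")
        return [
            ScalarTerm("d", calf, rel_c),
            RandomRegressionTerm("m", dam, x, rel_d),
            RandomRegressionTerm("pe", dam, x, None),
            ScalarTerm("hym", df["hym"].to_numpy()),
        ]

    def fit(self, data: pd.DataFrame, y=None):
        df = data.reset_index(drop=True)
        yy = df["biw_kg"].to_numpy(dtype=float) if y is None else np.asarray(y, dtype=float)
        X, names = fixed_design(df, self.covariate)
        res = reml_fit(X, yy, self._terms(df), start=self.start, max_iter=self.max_iter,
                       tol_param=self.tol_param, tol_logl=self.tol_logl)
        self.result_ = res
        self.x_names_ = names
        self.beta_ = res.beta
        self.coef_, self.coef_se_, self.p_value_ = _wald(res.beta, res.beta_cov, names, self.covariate)
        self.v_d_ = res.component("v_d")
        self.K_m_ = res.cov2("m")
        self.K_pe_ = res.cov2("pe")
        self.v_hym_ = res.component("v_hym")
        self.v_e_ = res.component("v_e")
        self.loglik_ = res.loglik
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        return self


def run_model1_battery(data: pd.DataFrame, covariates=None, **fit_kwargs) -> pd.DataFrame:
    """Fit model 1 once per heat-load covariate (the 13 consecutive runs).

    Failures in one run are recorded in the ``error`` column and do not abort
    the battery.  Returns one row per covariate with the regression
    coefficient (kg per scaled unit), its SE, Wald p-value, the variance
    components and the restricted log-likelihood.
    """
    covariates = list(ALL_COVARIATES if covariates is None else covariates)
    rows = []
    for cov in covariates:
        row = {"covariate": cov}
        try:
            m = FixedRegressionModel(covariate=cov, **fit_kwargs).fit(data)
            row.update(
                coef=m.coef_, se=m.coef_se_, p_value=m.p_value_, loglik=m.loglik_,
                n_iter=m.n_iter_, error="", **m.varcomp_,
            )
        except Exception as err:  # noqa: BLE001 - per-run isolation is the contract
            row.update(coef=np.nan, se=np.nan, p_value=np.nan, error=str(err))
        rows.append(row)
    return pd.DataFrame(rows)
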