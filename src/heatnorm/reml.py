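"""Average-information REML for linear mixed models with reaction-norm terms.

The engine works on the record-level phenotypic covariance

    V(θ) = Σ_i θ_i · V_i + v_e · I,

where every variance parameter enters linearly.  A scalar random term u with
incidence Z and (optional) relationship S contributes θ·Z S Z'; a random
intercept+slope pair over a grouping factor with per-record covariate x
contributes three parameters (v_int, c_is, v_slope) whose structure matrices
are D, D∘(x⊕x) and D∘(xx') with D the group relationship expanded to
records.  Because the number of records n is far below the number of
random-effect levels times two, dense Cholesky of V (LAPACK dpotrf/dpotri)
beats a sparse mixed-model-equations factorisation at the scales this
package targets.

Each iteration forms P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹ and takes a Newton step
with the average-information matrix AI_ij = ½ (Py)'V_i P V_j (Py) and score
g_i = −½ [tr(P V_i) − (Py)'V_i(Py)].  Steps that leave the parameter cone
(negative scalar variances, non-PSD 2×2 blocks) or decrease the restricted
likelihood are halved; as a last resort the offending 2×2 block is projected
onto the PSD cone by eigenvalue clipping.  Accepted iterations therefore
never decrease logL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg.lapack import dpotri

__all__ = [
    "ScalarTerm",
    "RandomRegressionTerm",
    "REMLResult",
    "reml_fit",
    "restricted_loglik",
    "default_start",
]


def _codes(groups) -> tuple[np.ndarray, int]:
    """Integer level codes for a grouping vector (order of first appearance)."""
    g = np.asarray(groups)
    _, codes = np.unique(g, return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1


@dataclass
class ScalarTerm:
    """One variance parameter: contribution θ · Z S Z'.

    ``groups`` maps each record to a level; ``relationship`` (level × level,
    dense) defaults to the identity (i.i.d. levels).
    """

    name: str
    groups: np.ndarray
    relationship: np.ndarray | None = None

    def structures(self, n: int) -> list[np.ndarray]:
        codes, q = _codes(self.groups)
        if self.relationship is None:
            D = (codes[:, None] == codes[None, :]).astype(float)
        else:
            S = np.asarray(self.relationship, dtype=float)
            if S.shape != (q, q):
                raise ValueError(f"term {self.name}: relationship is {S.shape}, need {(q, q)}")
            D = S[np.ix_(codes, codes)]
        return [D]

    @property
    def param_names(self) -> list[str]:
        return [f"v_{self.name}"]

    n_params = 1


@dataclass
class RandomRegressionTerm:
    """Correlated random intercept + slope per level (reaction norm).

    Parameters are the 2×2 covariance function (v_int, c_is, v_slope);
    ``covariate`` holds the per-record gradient value x.
    """

    name: str
    groups: np.ndarray
    covariate: np.ndarray
    relationship: np.ndarray | None = None

    def structures(self, n: int) -> list[np.ndarray]:
        x = np.asarray(self.covariate, dtype=float)
        if x.shape != (n,):
            raise ValueError(f"term {self.name}: covariate length {x.shape} != {n}")
        D = ScalarTerm(self.name, self.groups, self.relationship).structures(n)[0]
        return [D, D * (x[:, None] + x[None, :]), D * np.outer(x, x)]

    @property
    def param_names(self) -> list[str]:
        return [f"{self.name}_v_int", f"{self.name}_c_is", f"{self.name}_v_slope"]

    n_params = 3


@dataclass
class REMLResult:
    theta: np.ndarray
    param_names: list[str]
    blocks: list[tuple[str, list[int]]]
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    ai: np.ndarray
    gradient: np.ndarray
    n_iter: int
    converged: bool
    trace: list[dict] = field(default_factory=list)

    def component(self, name: str) -> float:
        return float(self.theta[self.param_names.index(name)])

    def cov2(self, term_name: str) -> np.ndarray:
        v0 = self.component(f"{term_name}_v_int")
        c = self.component(f"{term_name}_c_is")
        v1 = self.component(f"{term_name}_v_slope")
        return np.array([[v0, c], [c, v1]])

    @property
    def ai_inv(self) -> np.ndarray:
        """Asymptotic covariance of the variance parameters."""
        try:
            return np.linalg.inv(self.ai)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(self.ai)


def _assemble(terms, n):
    mats, names, blocks = [], [], []
    for t in terms:
        start = len(names)
        mats.extend(t.structures(n))
        names.extend(t.param_names)
        kind = "cov2" if t.n_params == 3 else "scalar"
        blocks.append((kind, list(range(start, start + t.n_params))))
    # residual is always the last parameter
    names.append("v_e")
    blocks.append(("scalar", [len(names) - 1]))
    return mats, names, blocks


def default_start(y, terms) -> np.ndarray:
    """Half the phenotypic variance to the residual, the rest spread equally
    over the random terms; 2×2 blocks start diagonal with zero covariance."""
    vy = float(np.var(np.asarray(y, dtype=float), ddof=1))
    share = 0.5 * vy / max(len(terms), 1)
    theta = []
    for t in terms:
        if t.n_params == 3:
            theta.extend([share, 0.0, share])
        else:
            theta.append(share)
    theta.append(0.5 * vy)
    return np.array(theta)


def _project(theta, blocks, floor):
    """Clamp scalar variances and clip 2×2 blocks onto the PSD cone."""
    th = theta.copy()
    for kind, idx in blocks:
        if kind == "scalar":
            th[idx[0]] = max(th[idx[0]], floor)
        else:
            i0, ic, i1 = idx
            K = np.array([[th[i0], th[ic]], [th[ic], th[i1]]])
            w, Q = np.linalg.eigh(K)
            if w[0] < floor:
                K = (Q * np.maximum(w, floor)) @ Q.T
                th[i0], th[ic], th[i1] = K[0, 0], K[0, 1], K[1, 1]
    return th


def _in_cone(theta, blocks, floor):
    for kind, idx in blocks:
        if kind == "scalar":
            if theta[idx[0]] < floor:
                return False
        else:
            i0, ic, i1 = idx
            if theta[i0] < floor or theta[i1] < 0 or theta[ic] ** 2 > theta[i0] * theta[i1]:
                return False
    return True


# --- unconstrained parametrisation -----------------------------------------
# scalars: θ = exp(φ); 2×2 blocks: K = LL' with L = [[e^a, 0], [b, e^c]], i.e.
# θ00 = e^{2a}, θ01 = b·e^a, θ11 = b² + e^{2c}.  Keeps every iterate inside
# the PSD cone without projections, so damped Newton steps can follow the
# likelihood ridge even when the optimum sits on (or near) the boundary.


def _theta_to_phi(theta, blocks, floor):
    th = _project(theta, blocks, 2.0 * floor)
    phi = np.empty_like(th)
    for kind, idx in blocks:
        if kind == "scalar":
            phi[idx[0]] = np.log(th[idx[0]])
        else:
            i0, ic, i1 = idx
            l00 = np.sqrt(th[i0])
            b = th[ic] / l00
            l11 = np.sqrt(max(th[i1] - b * b, floor))
            phi[i0], phi[ic], phi[i1] = np.log(l00), b, np.log(l11)
    return phi


def _phi_to_theta(phi, blocks):
    th = np.empty_like(phi)
    for kind, idx in blocks:
        if kind == "scalar":
            th[idx[0]] = np.exp(phi[idx[0]])
        else:
            i0, ic, i1 = idx
            l00, b, l11 = np.exp(phi[i0]), phi[ic], np.exp(phi[i1])
            th[i0] = l00 * l00
            th[ic] = b * l00
            th[i1] = b * b + l11 * l11
    return th


def _jacobian(phi, blocks):
    """J[i, j] = ∂θ_i/∂φ_j (block diagonal)."""
    m = len(phi)
    J = np.zeros((m, m))
    for kind, idx in blocks:
        if kind == "scalar":
            J[idx[0], idx[0]] = np.exp(phi[idx[0]])
        else:
            i0, ic, i1 = idx
            l00, b, l11 = np.exp(phi[i0]), phi[ic], np.exp(phi[i1])
            J[i0, i0] = 2.0 * l00 * l00
            J[ic, i0] = b * l00
            J[ic, ic] = l00
            J[i1, ic] = 2.0 * b
            J[i1, i1] = 2.0 * l11 * l11
    return J


def _loglik_only(X, y, V) -> float:
    """Restricted log-likelihood via one Cholesky (no explicit inverse)."""
    n, p = X.shape
    c = sla.cho_factor(V, lower=True)
    ldet_V = 2.0 * np.sum(np.log(np.diag(c[0])))
    VinvX = sla.cho_solve(c, X)
    Vinvy = sla.cho_solve(c, y)
    XtVinvX = X.T @ VinvX
    cx = sla.cho_factor(XtVinvX, lower=True)
    ldet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    Xty = X.T @ Vinvy
    beta = sla.cho_solve(cx, Xty)
    yPy = float(y @ Vinvy - Xty @ beta)
    return -0.5 * ((n - p) * np.log(2.0 * np.pi) + ldet_V + ldet_X + yPy)


def _chol_pieces(X, y, V):
    """Cholesky-based V⁻¹, P, Py and restricted log-likelihood."""
    n, p = X.shape
    c, low = sla.cho_factor(V, lower=True)
    ldet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv, info = dpotri(c, lower=True)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cx = sla.cho_factor(XtVinvX, lower=True)
    ldet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    W = sla.cho_solve(cx, VinvX.T)  # (X'V⁻¹X)⁻¹ X'V⁻¹
    P = Vinv - VinvX @ W
    Py = P @ y
    yPy = float(y @ Py)
    logl = -0.5 * ((n - p) * np.log(2.0 * np.pi) + ldet_V + ldet_X + yPy)
    beta = W @ y
    beta_cov = sla.cho_solve(cx, np.eye(p))
    return P, Py, logl, beta, beta_cov


def reml_fit(
    X,
    y,
    terms,
    start=None,
    max_iter: int = 200,
    tol_param: float = 1e-8,
    tol_logl: float = 1e-6,
    verbose: bool = False,
):
    """Fit variance components by average-information REML.

    Parameters
    ----------
    X : (n, p) dense full-column-rank fixed-effect design.
    y : (n,) response.
    terms : sequence of ScalarTerm / RandomRegressionTerm.
    start : optional initial θ (see :func:`default_start`).

    Raises ``RuntimeError`` (with the iteration trace attached) if not
    converged within ``max_iter``.
    """
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")
    mats, names, blocks = _assemble(terms, n)
    vy = float(np.var(y, ddof=1))
    floor = 1e-8 * vy
    theta = default_start(y, terms) if start is None else np.asarray(start, dtype=float).copy()
    if not _in_cone(theta, blocks, 0.0):
        import warnings

        warnings.warn("starting values outside the PSD cone; projected", RuntimeWarning,
                      stacklevel=2)
        theta = _project(theta, blocks, floor)
    I_n = np.eye(n)

    def build_V(th):
        V = th[-1] * I_n
        for m, t in zip(mats, th[:-1]):
            if t != 0.0:
                V += t * m
        return V

    phi = _theta_to_phi(theta, blocks, floor)
    theta = _phi_to_theta(phi, blocks)
    P, Py, logl, beta, beta_cov = _chol_pieces(X, y, build_V(theta))
    trace = [{"iter": 0, "loglik": logl, "theta": theta.copy()}]
    converged = False
    grad = np.zeros(len(names))
    ai = np.eye(len(names))
    lam = 1e-3  # Levenberg-Marquardt damping on the transformed AI matrix
    full = mats + [I_n]
    plateau = 0
    it = 0
    for it in range(1, max_iter + 1):
        grad = np.array(
            [-0.5 * (np.einsum("ij,ij->", P, M) - Py @ (M @ Py)) for M in full]
        )
        F = np.column_stack([M @ Py for M in full])
        PF = P @ F
        ai = 0.5 * (F.T @ PF)
        ai = 0.5 * (ai + ai.T)
        J = _jacobian(phi, blocks)
        grad_u = J.T @ grad
        ai_u = J.T @ ai @ J
        scale = np.maximum(np.diag(ai_u), 1e-8 * max(np.diag(ai_u).max(), 1.0))

        accepted = False
        dphi = np.zeros_like(phi)
        for _ in range(30):  # LM: inflate damping until an uphill step appears
            try:
                dphi = np.linalg.solve(ai_u + lam * np.diag(scale), grad_u)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            dphi = np.clip(dphi, -4.0, 4.0)  # exp-scale safety
            cand_phi = np.clip(phi + dphi, np.log(floor) if floor > 0 else -40.0, 40.0)
            cand_theta = _phi_to_theta(cand_phi, blocks)
            try:
                logl_c = _loglik_only(X, y, build_V(cand_theta))
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            if logl_c > logl - 1e-12:
                # ridge acceleration: extend the step while logL keeps rising
                for _ in range(4):
                    ext_phi = np.clip(cand_phi + dphi, np.log(floor) if floor > 0 else -40.0, 40.0)
                    ext_theta = _phi_to_theta(ext_phi, blocks)
                    try:
                        logl_e = _loglik_only(X, y, build_V(ext_theta))
                    except np.linalg.LinAlgError:
                        break
                    if logl_e <= logl_c:
                        break
                    cand_phi, cand_theta, logl_c = ext_phi, ext_theta, logl_e
                phi, theta = cand_phi, cand_theta
                dlogl = logl_c - logl
                accepted = True
                lam = max(lam / 10.0, 1e-8)
                break
            lam *= 10.0
        trace.append({"iter": it, "loglik": logl, "theta": theta.copy(), "lambda": lam})
        if verbose:
            print(f"iter {it:3d} logL {logl:.6f} lambda {lam:.3g}")
        if not accepted:
            converged = True  # no uphill step at any damping: stationary point
            break
        P, Py, logl, beta, beta_cov = _chol_pieces(X, y, build_V(theta))
        rel = np.max(np.abs(dphi))
        plateau = plateau + 1 if abs(dlogl) < tol_logl else 0
        if rel < tol_param or (lam <= 1e-2 and abs(dlogl) < tol_logl) or plateau >= 3:
            converged = True
            break
    if not converged:
        err = RuntimeError(f"AI-REML did not converge in {max_iter} iterations")
        err.trace = trace  # type: ignore[attr-defined]
        raise err
    return REMLResult(
        theta=theta,
        param_names=names,
        blocks=blocks,
        loglik=logl,
        beta=beta,
        beta_cov=beta_cov,
        ai=ai,
        gradient=grad,
        n_iter=it,
        converged=converged,
        trace=trace,
    )


def restricted_loglik(X, y, terms, theta) -> float:
    """Restricted log-likelihood via the mixed-model-equations factorisation.

    Builds the coefficient matrix C = W'R⁻¹W + diag(0, G⁻¹) with W = [X Z]
    and uses ln|V| + ln|X'V⁻¹X| = ln|R| + ln|G| + ln|C|.  Exact and
    independent of the record-level route used inside :func:`reml_fit`;
    intended for toy-to-desk scale model comparison.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n, p = X.shape
    v_e = theta[-1]
    if v_e <= 0:
        raise ValueError("residual variance must be positive")
    Zs, Gs = [], []
    k = 0
    for t in terms:
        codes, q = _codes(t.groups)
        Zi = np.zeros((n, q))
        Zi[np.arange(n), codes] = 1.0
        S = np.eye(q) if t.relationship is None else np.asarray(t.relationship, dtype=float)
        if t.n_params == 1:
            Zs.append(Zi)
            Gs.append(theta[k] * S)
            k += 1
        else:
            x = np.asarray(t.covariate, dtype=float)
            Zs.append(np.hstack([Zi, Zi * x[:, None]]))
            K = np.array([[theta[k], theta[k + 1]], [theta[k + 1], theta[k + 2]]])
            Gs.append(np.kron(K, S))
            k += 3
    Z = np.hstack(Zs) if Zs else np.zeros((n, 0))
    G = sla.block_diag(*Gs) if Gs else np.zeros((0, 0))
    q = Z.shape[1]
    Wm = np.hstack([X, Z])
    sign, ldet_G = np.linalg.slogdet(G)
    if sign <= 0:
        raise np.linalg.LinAlgError("random-effect covariance G is singular")
    C = Wm.T @ Wm / v_e
    G_inv = np.linalg.inv(G)
    C[p:, p:] += G_inv
    cc = sla.cho_factor(C, lower=True)
    ldet_C = 2.0 * np.sum(np.log(np.diag(cc[0])))
    rhs = Wm.T @ y / v_e
    sol = sla.cho_solve(cc, rhs)
    yPy = float(y @ y / v_e - sol @ rhs)
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi) + n * np.log(v_e) + ldet_G + ldet_C + yPy
    )
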