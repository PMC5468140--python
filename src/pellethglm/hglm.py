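"""Binomial hierarchical GLM with CAR-structured spatial random effects.

The model for presence y_i in {0,1} at plot-year unit i is

    logit(p_i) = x_i' beta + u_i,      u ~ N(0, tau * (I - rho*D)^{-1}),

with D the binary 350-m neighborhood matrix.  Estimation follows the
h-likelihood approach for hierarchical GLMs: for given dispersion
parameters (tau, rho), (beta, u) maximize the joint (hierarchical)
likelihood by Newton iteration on the augmented system, and (tau, rho)
maximize an adjusted profile criterion -- the restricted likelihood of the
model linearized at the current fit (working response
z = eta + (y - mu)/(mu(1-mu)), weights mu(1-mu)) -- by a derivative-free
search with the inner Newton refit nested inside each evaluation.
Inference on beta is quasi-likelihood: a dispersion phi of the mean model
is estimated from leverage-corrected squared residuals and multiplies the
variance of beta_hat, relaxing the binomial mean-variance relation
(phi < 1 = underdispersion, which rare binary presence data typically
show under this model family).

All linear algebra runs on sparse precision matrices; dense operations are
confined to small problems and tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit, logit

from ._solver import BlockSchurSystem
from .design import AdjacencyMatrix
from .frames import ModelFrame
from .survey import round_half_away

logger = logging.getLogger(__name__)

__all__ = [
    "CARParams",
    "HGLMFit",
    "rho_valid_range",
    "car_precision",
    "car_covariance",
    "fit_spatial_binomial_hglm",
    "wald_test",
    "term_pvalue",
    "odds_change_per_unit",
]


@dataclass(frozen=True)
class CARParams:
    """Dispersion parameters of the CAR random-effect covariance
    tau * (I - rho*D)^{-1}."""

    tau: float
    rho: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def _as_sparse_sym(D) -> sp.csr_matrix:
    if isinstance(D, AdjacencyMatrix):
        return D.matrix
    M = sp.csr_matrix(D, dtype=float)
    if (abs(M - M.T) > 1e-12).nnz:
        raise ValueError("D must be symmetric")
    if np.any(M.diagonal() != 0):
        raise ValueError("D must have a zero diagonal")
    return M


def _eigenvalues(D) -> np.ndarray:
    if isinstance(D, AdjacencyMatrix):
        return D.eigenvalues()
    return np.linalg.eigvalsh(_as_sparse_sym(D).toarray())


def rho_valid_range(D) -> tuple[float, float]:
    """Open interval of rho keeping I - rho*D positive definite.

    Returns (1/lambda_min, 1/lambda_max) from the extreme eigenvalues of D;
    an edgeless D leaves rho unconstrained and yields (-inf, inf).
    """
    M = _as_sparse_sym(D)
    if M.nnz == 0:
        return (-np.inf, np.inf)
    lam = _eigenvalues(D)
    lam_min, lam_max = float(lam.min()), float(lam.max())
    # any graph with >=1 edge has lam_min < 0 < lam_max (zero trace)
    return (1.0 / lam_min, 1.0 / lam_max)


def car_precision(params: CARParams, D) -> sp.csr_matrix:
    """Sparse CAR precision Q = (I - rho*D)/tau, validated positive definite."""
    M = _as_sparse_sym(D)
    lo, hi = rho_valid_range(D)
    if not (lo < params.rho < hi):
        raise ValueError(
            f"rho={params.rho} outside the positive-definite range ({lo}, {hi})")
    n = M.shape[0]
    return ((sp.identity(n, format="csr") - params.rho * M) / params.tau).tocsr()


def car_covariance(params: CARParams, D) -> np.ndarray:
    """Dense CAR covariance tau * (I - rho*D)^{-1}.

    Materializing the inverse is intended for small graphs and testing; the
    fitting and simulation code paths work with :func:`car_precision`.
    """
    Q = car_precision(params, D).toarray()
    return np.linalg.inv(Q)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class HGLMFit:
    """Result of a spatial binomial HGLM fit."""

    beta: pd.Series
    se_beta: pd.Series
    cov_beta: np.ndarray
    u: np.ndarray
    tau: float
    rho: float
    phi: float
    converged: bool
    n_iter: int
    n_obs: int
    term_columns: dict
    references: dict = field(default_factory=dict)
    eta: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)
    sigma2_extra: float | None = None
    u_extra: np.ndarray | None = None
    p_eff: float = np.nan
    laplace: float = np.nan

    @property
    def columns(self) -> list[str]:
        return list(self.beta.index)

    def to_dict(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se_beta": {k: float(v) for k, v in self.se_beta.items()},
            "tau": float(self.tau),
            "rho": float(self.rho),
            "phi": float(self.phi),
            "sigma2_extra": None if self.sigma2_extra is None else float(self.sigma2_extra),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_obs": int(self.n_obs),
        }


def _inner_newton(y, B, Q, P_B, blocks, b0, u0, *, max_iter=80, tol=1e-9):
    """Maximize the joint h-likelihood over (border coefs, u) for fixed
    dispersions, via damped Newton steps on the block-Schur system."""
    b, u = b0.copy(), u0.copy()

    def h_value(bv, uv):
        eta = B @ bv + uv
        return float(np.sum(y * eta - np.logaddexp(0.0, eta))
                     - 0.5 * uv @ (Q @ uv) - 0.5 * bv @ (P_B @ bv))

    h = h_value(b, u)
    system = None
    converged = False
    for _ in range(max_iter):
        eta = B @ b + u
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        system = BlockSchurSystem(B, w, Q, P_B, blocks)
        resid = y - mu
        grad_b = B.T @ resid - P_B @ b
        grad_u = resid - Q @ u
        db, du = system.solve(grad_b, grad_u)
        t = 1.0
        for _ in range(40):
            cand_b, cand_u = b + t * db, u + t * du
            h_new = h_value(cand_b, cand_u)
            if h_new >= h - 1e-12:
                break
            t *= 0.5
        else:
            break
        moved = t * max(np.max(np.abs(db)), np.max(np.abs(du)))
        b, u, h = cand_b, cand_u, h_new
        scale = 1.0 + max(np.max(np.abs(b)), np.max(np.abs(u)))
        if moved < tol * scale:
            converged = True
            break
    eta = B @ b + u
    mu = expit(eta)
    return b, u, h, system, eta, mu, converged


def fit_spatial_binomial_hglm(
    frame: ModelFrame,
    adjacency: AdjacencyMatrix,
    *,
    tau0: float = 1.0,
    rho0: float | None = None,
    fix_tau: float | None = None,
    fix_rho: float | None = None,
    Z_extra: np.ndarray | sp.spmatrix | None = None,
    sigma2_extra0: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-6,
    dispersion: str = "pearson",
) -> HGLMFit:
    """Fit the spatial binomial HGLM by h-likelihood.

    Nelder-Mead maximizes the adjusted profile (restricted) likelihood of
    the linearized model over (tau, rho[, sigma2]); every evaluation refits
    (beta, u) by warm-started Newton maximization of the joint
    h-likelihood, so the returned estimates are self-consistent.
    Deterministic given inputs and options.

    Parameters
    ----------
    frame
        Model frame; its ``row_index`` selects the adjacency units used.
    adjacency
        Neighborhood structure over all candidate units.
    fix_tau, fix_rho
        Fix a dispersion parameter instead of estimating it.  ``fix_tau``
        near zero with an edgeless ``adjacency`` reduces the fit to ordinary
        logistic regression.
    Z_extra
        Optional design for an additional exchangeable (iid normal) random
        intercept, e.g. year dummies for a random-year sensitivity refit.
    dispersion
        "pearson" (default) or "deviance": estimator of the quasi-dispersion
        phi of the mean model.  Both divide by the leverage-corrected
        residual degrees of freedom.  On rare binary outcomes the deviance
        variant sits well below 1 even for well-specified data.
    """
    y = np.asarray(frame.y, dtype=float)
    n, p = frame.X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    if np.all(y == 0) or np.all(y == 1):
        raise ValueError("degenerate response: all observations identical")

    D = adjacency
    if D.n != n:
        D = D.subset(frame.row_index)
    Dm = D.matrix
    blocks = D._year_blocks()
    edgeless = Dm.nnz == 0
    lam = None if edgeless else D.eigenvalues()
    lo, hi = (-np.inf, np.inf) if edgeless else (1.0 / lam.min(), 1.0 / lam.max())

    if edgeless and fix_rho is None:
        fix_rho = 0.0  # rho has no effect without edges
    if rho0 is None:
        rho0 = 0.0 if edgeless else min(hi, 0.1) / 2.0

    q = 0
    if Z_extra is not None:
        Zd = np.asarray(sp.csr_matrix(Z_extra, dtype=float).todense())
        q = Zd.shape[1]
        B = np.column_stack([frame.X, Zd])
    else:
        B = np.asarray(frame.X, dtype=float)

    # free dispersion parameters, in unconstrained coordinates
    margin = 1e-6
    free: list[str] = []
    if fix_tau is None:
        free.append("tau")
    if fix_rho is None:
        free.append("rho")
    if q:
        free.append("sigma2")

    def rho_from_s(s):
        # logistic map onto the open PD interval, clamped 1e-6 inside
        r = lo + (hi - lo) * expit(s)
        return float(np.clip(r, lo + margin * (hi - lo), hi - margin * (hi - lo)))

    def s_from_rho(r):
        frac = np.clip((r - lo) / (hi - lo), 1e-6, 1 - 1e-6)
        return float(logit(frac))

    def unpack(theta):
        i = 0
        tau = fix_tau
        rho = fix_rho
        s2 = None
        # log-scale parameters are clipped so boundary collapses (e.g. a
        # zero variance component) stay numerically finite
        if "tau" in free:
            tau = float(np.exp(np.clip(theta[i], -20.0, 10.0))); i += 1
        if "rho" in free:
            rho = rho_from_s(theta[i]); i += 1
        if q:
            s2 = float(np.exp(np.clip(theta[i], -20.0, 10.0))); i += 1
        return tau, rho, s2

    I_n = sp.identity(n, format="csr")

    def precisions(tau, rho, s2):
        """CAR precision Q, border prior P_B, and log|prior precision|."""
        Qc = ((I_n - rho * Dm) / tau).tocsr()
        logdet = -n * np.log(tau)
        if lam is not None:
            vals = 1.0 - rho * lam
            if np.any(vals <= 0):
                return None, None, None
            logdet += float(np.sum(np.log(vals)))
        P_B = np.zeros((p + q, p + q))
        if q:
            P_B[p:, p:] = np.eye(q) / s2
            logdet += -q * np.log(s2)
        return Qc, P_B, logdet

    b_cur = np.zeros(p + q)
    if "intercept" in frame.columns:
        ybar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        b_cur[frame.columns.index("intercept")] = logit(ybar)
    u_cur = np.zeros(n)

    theta0 = []
    if "tau" in free:
        theta0.append(np.log(tau0))
    if "rho" in free:
        theta0.append(s_from_rho(rho0))
    if q:
        theta0.append(np.log(sigma2_extra0))
    theta = np.asarray(theta0)

    state = {"b": b_cur, "u": u_cur, "nfev": 0}

    def profile_objective(theta_try):
        """Negative adjusted profile likelihood of the linearized model.

        For the dispersions under trial, (beta, u) are refit by Newton
        (warm-started), the model is linearized at the fit (working
        response z = eta + (y-mu)/w, weights w = mu(1-mu)), and the
        restricted likelihood of that weighted linear mixed model is
        evaluated via the augmented least-squares identity:

            -2 l_R = log|A| - log|P| + (y-mu)'W^{-1}(y-mu) + u'Qu  (+ const)

        with A the augmented information matrix and P the full prior
        precision.  Minimized over (tau, rho[, sigma2]) by Nelder-Mead.
        """
        tau, rho, s2 = unpack(theta_try)
        Qc, P_B, logdetP = precisions(tau, rho, s2)
        if Qc is None:
            return np.inf
        try:
            b_new, u_new, h, system, eta, mu, ok = _inner_newton(
                y, B, Qc, P_B, blocks, state["b"], state["u"])
        except (RuntimeError, np.linalg.LinAlgError):
            return np.inf
        state["b"], state["u"] = b_new, u_new
        state["nfev"] += 1
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        rss = float(np.sum((y - mu) ** 2 / w) + u_new @ (Qc @ u_new)
                    + b_new @ (P_B @ b_new))
        return 0.5 * (system.logdet - logdetP + rss)

    n_outer = 0
    inner_ok = True
    opt_ok = True
    if free:
        simplex = [theta] + [theta + 0.7 * e for e in np.eye(len(theta))]
        res = minimize(profile_objective, theta, method="Nelder-Mead",
                       options={"xatol": tol * 10, "fatol": 1e-8,
                                "maxiter": max_iter * max(1, len(theta)),
                                "initial_simplex": np.asarray(simplex)})
        theta = res.x
        opt_ok = bool(res.success)
        n_outer = int(res.nit)
    tau_hat, rho_hat, s2_hat = unpack(theta)
    b_cur, u_cur = state["b"], state["u"]

    if "rho" in free and np.isfinite(lo):
        frac = (rho_hat - lo) / (hi - lo)
        if frac <= 2 * margin or frac >= 1 - 2 * margin:
            warnings.warn(
                f"rho search hit the edge of its valid range ({lo:.4g}, {hi:.4g}); "
                f"clamped inward", RuntimeWarning)

    Qc, P_B, logdetP = precisions(tau_hat, rho_hat, s2_hat)
    b_cur, u_cur, h, system, eta, mu, newton_ok = _inner_newton(
        y, B, Qc, P_B, blocks, b_cur, u_cur, tol=1e-10)
    inner_ok = inner_ok and newton_ok
    criterion = h + 0.5 * logdetP - 0.5 * system.logdet

    if np.max(np.abs(eta)) > 30:
        warnings.warn("extreme linear predictor: possible (quasi-)separation",
                      RuntimeWarning)

    Ainv_border = system.border_cov()
    Ainv_bb = 0.5 * (Ainv_border[:p, :p] + Ainv_border[:p, :p].T)

    # effective number of mean-model parameters:
    # p_eff = trace(A^{-1} [B I]'W[B I]) = (p+q+n) - trace(A^{-1} prior)
    tr_prior = system.trace_uu_times(Qc)
    if q:
        tr_prior += float(np.trace(Ainv_border[p:, p:]) / s2_hat)
    p_eff = (p + q + n) - tr_prior

    dof = max(n - p_eff, 1.0)
    if dispersion == "pearson":
        phi = float(np.sum((y - mu) ** 2 / np.clip(mu * (1 - mu), 1e-10, None)) / dof)
    elif dispersion == "deviance":
        with np.errstate(divide="ignore", invalid="ignore"):
            d = 2.0 * (np.where(y > 0, y * np.log(np.clip(y / mu, 1e-300, None)), 0.0)
                       + np.where(y < 1, (1 - y) * np.log(
                           np.clip((1 - y) / (1 - mu), 1e-300, None)), 0.0))
        phi = float(np.sum(d) / dof)
    else:
        raise ValueError(f"unknown dispersion estimator {dispersion!r}")

    cov_beta = phi * Ainv_bb
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))

    beta_hat = pd.Series(b_cur[:p], index=frame.columns)
    fit = HGLMFit(
        beta=beta_hat,
        se_beta=pd.Series(se, index=frame.columns),
        cov_beta=cov_beta,
        u=u_cur,
        tau=float(tau_hat),
        rho=float(rho_hat),
        phi=phi,
        converged=bool(inner_ok and opt_ok),
        n_iter=n_outer,
        n_obs=n,
        term_columns=frame.term_columns,
        references=dict(frame.references),
        eta=eta,
        mu=mu,
        sigma2_extra=s2_hat,
        u_extra=b_cur[p:] if q else None,
        p_eff=float(p_eff),
        laplace=float(criterion),
    )
    if not fit.converged:
        warnings.warn("HGLM fit did not fully converge", RuntimeWarning)
    return fit


# ---------------------------------------------------------------------------
# inference


def wald_test(fit: HGLMFit, term: str):
    """Wald test of a single coefficient: (estimate, SE, z, two-sided p)."""
    from scipy.stats import norm

    if term not in fit.beta.index:
        raise KeyError(f"unknown term {term!r}; have {list(fit.beta.index)}")
    est = float(fit.beta[term])
    se = float(fit.se_beta[term])
    z = est / se if se > 0 else np.inf * np.sign(est)
    pval = 2.0 * norm.sf(abs(z))
    return est, se, float(z), float(pval)


def term_pvalue(fit: HGLMFit, term: str, method: str = "max") -> float:
    """Term-level p-value for possibly multi-column terms.

    ``max``: the largest single-coefficient Wald p across the term's columns
    (reference-free levels of a factor).  ``joint``: Wald chi-square test of
    all the term's coefficients jointly.
    """
    from scipy.stats import chi2

    if term not in fit.term_columns:
        raise KeyError(f"unknown model term {term!r}")
    cols = fit.term_columns[term]
    names = [fit.columns[c] for c in cols]
    if method == "max":
        return max(wald_test(fit, nm)[3] for nm in names)
    if method == "joint":
        b = fit.beta.iloc[cols].to_numpy()
        V = fit.cov_beta[np.ix_(cols, cols)]
        stat = float(b @ np.linalg.solve(V, b))
        return float(chi2.sf(stat, df=len(cols)))
    raise ValueError(f"unknown term p-value method {method!r}")


def odds_change_per_unit(beta_interaction: float, convention: str = "exp_neg",
                         rounded: bool = True) -> float:
    """Percent decrease in the odds of presence per one-unit covariate step.

    The default convention reads a coefficient b as a decrease of
    100*(1 - exp(-b)) percent in the odds when moving one covariate unit in
    the direction that lowers the linear predictor (e.g. 100 m toward the
    turbines for a positive distance x phase interaction).  Alternatives:
    ``exp`` = 100*(exp(b) - 1), ``linear`` = 100*b.
    """
    b = float(beta_interaction)
    if not np.isfinite(b):
        raise ValueError("coefficient must be finite")
    if convention == "exp_neg":
        pct = 100.0 * (1.0 - np.exp(-b))
    elif convention == "exp":
        pct = 100.0 * (np.exp(b) - 1.0)
    elif convention == "linear":
        pct = 100.0 * b
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return round_half_away(pct) if rounded else pct
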