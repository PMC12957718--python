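"""Weighted binomial mixed models via penalised IRLS and a Laplace marginal.

The modelling unit is a Bernoulli observation whose log-likelihood
contribution is multiplied by an observation weight in [0, 1].  Random
terms may be scalar intercepts or correlated intercept+slope pairs; all
terms are crossed.  Estimation maximises the Laplace approximation to the
weighted marginal likelihood:

    log L(beta, theta) ~= sum_i w_i l_i(beta, b_hat)
                          - 1/2 b_hat' Sigma^-1 b_hat
                          - 1/2 log det(Sigma H_bb)

where b_hat is the joint penalised mode found by iteratively reweighted
least squares over (beta, b), H_bb = Z'WZ + Sigma^-1, and theta packs the
variance parameters (log standard deviations, log-Cholesky factors for
correlated pairs).  The outer optimisation over theta uses Nelder-Mead.

A small ridge (1e-4) on the fixed effects keeps separated fits finite;
coefficients beyond 15 on the logit scale are flagged as quasi-separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit

RIDGE_BETA = 1e-4
SEPARATION_LOGIT = 15.0
LOG_SD_BOUND = 8.0
# Weak gamma(shape, rate=0) penalty on random-effect Cholesky diagonals
# (penalised ML in the style of blme): keeps variance estimates off the
# zero boundary, where Wald intervals for means of few-level terms would
# otherwise collapse.  shape=1 disables the penalty.
SD_PENALTY_SHAPE = 2.0


def _sd_log_prior(chols) -> float:
    if SD_PENALTY_SHAPE == 1.0:
        return 0.0
    s = sum(float(np.sum(np.log(np.diag(L)))) for L in chols)
    return (SD_PENALTY_SHAPE - 1.0) * s


@dataclass
class RandomTerm:
    """One crossed random term.

    ``codes`` maps each observation to a level (0..n_levels-1); ``design``
    gives the within-level design, one column per correlated effect
    (``None`` means a plain intercept).
    """

    name: str
    codes: np.ndarray
    design: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.design is not None:
            self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
            if self.design.shape[0] != self.codes.shape[0]:
                self.design = self.design.T

    @property
    def k(self) -> int:
        return 1 if self.design is None else self.design.shape[1]

    @property
    def n_levels(self) -> int:
        return int(self.codes.max()) + 1 if len(self.codes) else 0


@dataclass
class GLMMFit:
    """Result of :func:`fit_glmm`."""

    beta: np.ndarray
    se_beta: np.ndarray
    vcov_beta: np.ndarray
    term_names: list
    fixed_names: list
    covariances: dict           # term name -> (k, k) covariance matrix
    blups: dict                 # term name -> (n_levels, k) conditional modes
    theta: np.ndarray
    loglik: float
    n_obs: int
    n_fixed: int
    n_theta: int
    converged: bool
    flags: list = field(default_factory=list)
    fitted: np.ndarray | None = None
    pointwise_loglik: np.ndarray | None = None
    n_outer_evals: int = 0
    # private plumbing for simulation / prediction
    _X: np.ndarray | None = None
    _terms: list | None = None
    _weights: np.ndarray | None = None
    _y: np.ndarray | None = None

    def sd(self, term: str, component: int = 0) -> float:
        return float(np.sqrt(self.covariances[term][component, component]))

    def variance(self, term: str, component: int = 0) -> float:
        return float(self.covariances[term][component, component])

    def correlation(self, term: str) -> float:
        cov = self.covariances[term]
        if cov.shape[0] < 2:
            raise ValueError(f"term {term!r} has a single component")
        return float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))

    def wald_interval(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return np.column_stack([self.beta - z * self.se_beta, self.beta + z * self.se_beta])


def _build_sparse_design(X: np.ndarray, terms: list[RandomTerm]):
    n = X.shape[0]
    blocks = [sparse.csc_matrix(X)]
    offsets = []
    q = 0
    for term in terms:
        k, levels = term.k, term.n_levels
        rows = np.repeat(np.arange(n), k)
        cols = (term.codes[:, None] * k + np.arange(k)[None, :]).ravel()
        if term.design is None:
            vals = np.ones(n * k)
        else:
            vals = term.design.ravel()
        blocks.append(sparse.csc_matrix((vals, (rows, cols)), shape=(n, levels * k)))
        offsets.append((q, q + levels * k))
        q += levels * k
    return sparse.hstack(blocks, format="csr"), offsets, q


def _n_theta(terms: list[RandomTerm]) -> int:
    return sum(1 if t.k == 1 else 3 for t in terms)


def _unpack_theta(theta: np.ndarray, terms: list[RandomTerm]):
    """theta -> list of (k,k) Cholesky factors L with Sigma = L L'."""
    chols = []
    i = 0
    for term in terms:
        if term.k == 1:
            chols.append(np.array([[np.exp(theta[i])]]))
            i += 1
        else:
            l11 = np.exp(theta[i])
            l21 = theta[i + 1]
            l22 = np.exp(theta[i + 2])
            chols.append(np.array([[l11, 0.0], [l21, l22]]))
            i += 3
    return chols


def _penalty_matrix(chols, terms, p):
    diags = []
    if p:
        diags.append(sparse.csc_matrix(np.eye(p) * RIDGE_BETA))
    for L, term in zip(chols, terms):
        sigma_inv = np.linalg.inv(L @ L.T)
        diags.append(sparse.kron(sparse.eye(term.n_levels), sigma_inv, format="csc"))
    if not diags:
        return sparse.csc_matrix((0, 0))
    return sparse.block_diag(diags, format="csc")


def _bernoulli_loglik(eta, y):
    # y*eta - log(1 + exp(eta)), stable
    return y * eta - np.logaddexp(0.0, eta)


def _pirls(y, A, P, w, u0, offset=0.0, max_iter=80, tol=1e-9):
    """Penalised IRLS over the coefficient vector u (eta = offset + A u)."""
    u = u0.copy()
    eta = offset + A @ u

    def objective(u, eta):
        return float(np.sum(w * _bernoulli_loglik(eta, y)) - 0.5 * u @ (P @ u))

    f = objective(u, eta)
    lu = None
    for _ in range(max_iter):
        mu = expit(eta)
        wirls = w * mu * (1 - mu) + 1e-12
        grad = A.T @ (w * (y - mu)) - P @ u
        H = (A.T @ A.multiply(wirls[:, None])).tocsc() + P
        lu = splu(H)
        delta = lu.solve(grad)
        step = 1.0
        for _ in range(25):
            u_new = u + step * delta
            eta_new = offset + A @ u_new
            f_new = objective(u_new, eta_new)
            if f_new >= f - 1e-12:
                break
            step *= 0.5
        improved = f_new - f
        u, eta, f = u_new, eta_new, f_new
        if abs(improved) < tol * (1.0 + abs(f)):
            break
    return u, eta, f, lu


def _laplace_loglik(theta, y, A, w, terms, p, q, state):
    chols = _unpack_theta(theta, terms)
    P = _penalty_matrix(chols, terms, p)
    u0 = state.get("u")
    if u0 is None:
        u0 = np.zeros(p + q)
    u, eta, _, _ = _pirls(y, A, P, w, u0)
    state["u"] = u
    mu = expit(eta)
    wirls = w * mu * (1 - mu) + 1e-12
    H = (A.T @ A.multiply(wirls[:, None])).tocsc() + P
    if q:
        Hbb = H[p:, p:].tocsc()
        lu_bb = splu(Hbb)
        logdet_hbb = float(np.sum(np.log(np.abs(lu_bb.U.diagonal()))))
    else:
        logdet_hbb = 0.0
    logdet_sigma = 0.0
    for L, term in zip(chols, terms):
        logdet_sigma += term.n_levels * 2.0 * float(np.sum(np.log(np.diag(L))))
    b = u[p:]
    pen = 0.0
    off = 0
    for L, term in zip(chols, terms):
        k, levels = term.k, term.n_levels
        bt = b[off:off + levels * k].reshape(levels, k)
        sigma_inv = np.linalg.inv(L @ L.T)
        pen += float(np.einsum("ij,jk,ik->", bt, sigma_inv, bt))
        off += levels * k
    ll = float(np.sum(w * _bernoulli_loglik(eta, y))) - 0.5 * pen
    ll -= 0.5 * (logdet_sigma + logdet_hbb)
    ll += _sd_log_prior(chols)
    # soft barrier keeping log-sds in a numerically sane range
    barrier = np.sum(np.clip(np.abs(theta) - LOG_SD_BOUND, 0, None) ** 2) * 100.0
    return ll - barrier, u, H


def _laplace_given_beta(beta, y, X, Z, w, chols, terms, Pb, state):
    """Full Laplace log-likelihood at fixed beta, with b profiled out.

    Unlike the theta-profiled objective (which takes beta from the joint
    PIRLS mode and ignores the dependence of the log-determinant on beta),
    this is the objective whose maximiser over beta matches a full Laplace
    fit; maximising it removes the attenuation of fixed effects familiar
    from nAGQ=0-style estimation.
    """
    offset = X @ beta
    b0 = state.get("b")
    if b0 is None:
        b0 = np.zeros(Z.shape[1])
    b, eta, _, _ = _pirls(y, Z, Pb, w, b0, offset=offset, tol=1e-12)
    state["b"] = b
    mu = expit(eta)
    wirls = w * mu * (1 - mu) + 1e-12
    Hbb = (Z.T @ Z.multiply(wirls[:, None])).tocsc() + Pb
    lu = splu(Hbb)
    logdet_hbb = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    logdet_sigma = sum(
        t.n_levels * 2.0 * float(np.sum(np.log(np.diag(L))))
        for L, t in zip(chols, terms)
    )
    ll = float(np.sum(w * _bernoulli_loglik(eta, y)))
    ll -= 0.5 * float(b @ (Pb @ b))
    ll -= 0.5 * (logdet_sigma + logdet_hbb)
    ll -= 0.5 * RIDGE_BETA * float(beta @ beta)
    ll += _sd_log_prior(chols)
    return ll, b


def _numerical_hessian(fn, x0, h: float = 0.02):
    """Central-difference Hessian (symmetric steps)."""
    k = len(x0)
    H = np.zeros((k, k))
    steps = h * np.maximum(1.0, np.abs(x0))
    f0 = fn(x0)
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fp[i] = fn(x0 + ei)
        fm[i] = fn(x0 - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            fpp = fn(x0 + ei + ej)
            fmm = fn(x0 - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * steps[i] * steps[j])
    return H


def fit_glmm(
    y,
    X,
    terms: list[RandomTerm],
    weights=None,
    fixed_names=None,
    theta0=None,
    maxfev: int = 300,
    fatol: float = 5e-3,
    xatol: float = 5e-3,
    polish_beta: bool = True,
    se_method: str = "joint",
) -> GLMMFit:
    """Fit a weighted Bernoulli GLMM with logit link.

    Parameters
    ----------
    y : (n,) 0/1 response.
    X : (n, p) fixed-effect design (caller includes the intercept column).
    terms : crossed random terms.
    weights : per-observation multipliers of the log-likelihood, in [0, 1];
        default all ones.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be 0/1")
    flags = []
    effective = w > 0
    if (not effective.any()) or np.ptp(y[effective]) == 0:
        flags.append("degenerate_response")

    A, offsets, q = _build_sparse_design(X, terms)
    n_theta = _n_theta(terms)
    if theta0 is None:
        theta0 = np.zeros(n_theta)

    state: dict = {}

    def neg(theta):
        ll, _, _ = _laplace_loglik(theta, y, A, w, terms, p, q, state)
        return -ll

    if n_theta:
        # Nelder-Mead with fresh-simplex restarts: the variance surface can
        # have narrow ridges (few levels in a term) that collapse the simplex.
        theta_hat = np.asarray(theta0, dtype=float)
        best = np.inf
        n_evals = 0
        converged = False
        for restart in range(4):
            # explicit simplex: scipy's default one is degenerate at 0
            spread = 0.5 if restart == 0 else 0.15
            simplex = np.vstack([theta_hat,
                                 theta_hat + spread * np.eye(n_theta)])
            res = minimize(
                neg,
                theta_hat,
                method="Nelder-Mead",
                options={"maxfev": maxfev, "fatol": fatol, "xatol": xatol,
                         "initial_simplex": simplex},
            )
            n_evals += int(res.nfev)
            improved = best - res.fun
            if res.fun < best:
                best, theta_hat = res.fun, res.x
            if improved < 0.1:
                converged = True
                break
    else:
        theta_hat = np.zeros(0)
        converged = True
        n_evals = 0

    ll, u, H = _laplace_loglik(theta_hat, y, A, w, terms, p, q, state)
    beta = u[:p]
    chols = _unpack_theta(theta_hat, terms)

    if polish_beta and q:
        Z = A[:, p:].tocsr()
        Pb = _penalty_matrix(chols, terms, 0)
        bstate = {"b": u[p:].copy()}

        def neg_beta(bvec):
            llb, _ = _laplace_given_beta(bvec, y, X, Z, w, chols, terms, Pb, bstate)
            return -llb

        res_b = minimize(
            neg_beta,
            beta,
            method="L-BFGS-B",
            jac="3-point",
            options={"maxiter": 40, "gtol": 0.05, "finite_diff_rel_step": 1e-4},
        )
        beta = res_b.x
        ll, b_hat = _laplace_given_beta(beta, y, X, Z, w, chols, terms, Pb, bstate)
        u = np.concatenate([beta, b_hat])
        eta = A @ u
        mu = expit(eta)
        wirls = w * mu * (1 - mu) + 1e-12
        P = _penalty_matrix(chols, terms, p)
        H = (A.T @ A.multiply(wirls[:, None])).tocsc() + P

    lu = splu(H.tocsc())
    eye_p = np.zeros((p + q, p))
    eye_p[:p, :p] = np.eye(p)
    cov_full = lu.solve(eye_p)
    vcov_beta = cov_full[:p, :]
    se_beta = np.sqrt(np.clip(np.diag(vcov_beta), 0, None))

    if se_method == "joint" and n_theta and q:
        # observed information of the Laplace marginal over (beta, theta),
        # by central finite differences; propagates variance-parameter
        # uncertainty into the fixed-effect standard errors.  Falls back to
        # the conditional-on-theta covariance where the joint information
        # is singular (variance parameters at the boundary).
        Zj = A[:, p:].tocsr()
        jstate = {"b": u[p:].copy()}

        def nll_joint(v):
            chols_v = _unpack_theta(v[p:], terms)
            Pb_v = _penalty_matrix(chols_v, terms, 0)
            ll_v, _ = _laplace_given_beta(v[:p], y, X, Zj, w, chols_v, terms,
                                          Pb_v, jstate)
            return -ll_v

        v0 = np.concatenate([beta, theta_hat])
        try:
            Hj = _numerical_hessian(nll_joint, v0)
            cov_j = np.linalg.pinv((Hj + Hj.T) / 2)
            var_j = np.diag(cov_j)[:p]
            if np.all(np.isfinite(var_j)) and np.all(var_j > 0):
                # joint uncertainty can only widen the conditional intervals
                var_c = np.diag(vcov_beta)
                vcov_beta = cov_j[:p, :p]
                se_beta = np.sqrt(np.maximum(var_j, var_c))
        except (np.linalg.LinAlgError, RuntimeError):
            pass

    if np.any(np.abs(beta) > SEPARATION_LOGIT):
        flags.append("quasi_separation")
    if not converged:
        flags.append("outer_optimizer_not_converged")

    chols = _unpack_theta(theta_hat, terms)
    covariances = {t.name: L @ L.T for t, L in zip(terms, chols)}
    blups = {}
    b = u[p:]
    off = 0
    for term in terms:
        size = term.n_levels * term.k
        blups[term.name] = b[off:off + size].reshape(term.n_levels, term.k)
        off += size

    eta = A @ u
    fitted = expit(eta)
    pointwise = _bernoulli_loglik(eta, y)

    return GLMMFit(
        beta=beta,
        se_beta=se_beta,
        vcov_beta=vcov_beta,
        term_names=[t.name for t in terms],
        fixed_names=list(fixed_names) if fixed_names is not None else [f"x{i}" for i in range(p)],
        covariances=covariances,
        blups=blups,
        theta=theta_hat,
        loglik=ll,
        n_obs=n,
        n_fixed=p,
        n_theta=n_theta,
        converged=converged and "degenerate_response" not in flags,
        flags=flags,
        fitted=fitted,
        pointwise_loglik=pointwise,
        n_outer_evals=n_evals,
        _X=X,
        _terms=terms,
        _weights=w,
        _y=y,
    )


def simulate_response(fit: GLMMFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a new 0/1 response from the fitted model (new random effects)."""
    eta = fit._X @ fit.beta
    for term in fit._terms:
        cov = fit.covariances[term.name]
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        b = rng.standard_normal((term.n_levels, term.k)) @ L.T
        z = np.ones((len(term.codes), 1)) if term.design is None else term.design
        eta = eta + np.sum(z * b[term.codes], axis=1)
    return (rng.random(len(eta)) < expit(eta)).astype(float)


def refit(fit: GLMMFit, y_new: np.ndarray, **kwargs) -> GLMMFit:
    """Refit the same design on a new response (parametric bootstrap)."""
    return fit_glmm(
        y_new,
        fit._X,
        fit._terms,
        weights=fit._weights,
        fixed_names=fit.fixed_names,
        theta0=fit.theta,
        **kwargs,
    )
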