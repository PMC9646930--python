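"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package's solvers: the graphical
lasso oracle is an ADMM splitting scheme built on eigendecompositions, the
lasso oracle solves the penalized objective with a generic smooth optimizer
over a positive/negative split, and the subset oracle enumerates supports.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def admm_glasso(S: np.ndarray, lam: float, rho: float = 1.0,
                iters: int = 20_000, tol: float = 1e-11) -> np.ndarray:
    """Maximize logdet(Theta) - tr(S Theta) - lam * ||Theta||_1(offdiag)."""
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(iters):
        d, Q = np.linalg.eigh(rho * (Z - U) - S)
        theta_eig = (d + np.sqrt(d ** 2 + 4 * rho)) / (2 * rho)
        Theta = (Q * theta_eig) @ Q.T
        Z_old = Z
        M = Theta + U
        Z = np.sign(M) * np.maximum(np.abs(M) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(M))
        U = U + Theta - Z
        if max(np.abs(Theta - Z).max(), rho * np.abs(Z - Z_old).max()) < tol:
            break
    return Z


def lasso_objective_solve(y: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    """Minimize (1/2n)||y - Xb||^2 + lam * ||b||_1 via L-BFGS-B on the
    standard positive/negative variable split (b = u - v, u, v >= 0)."""
    n, p = X.shape

    def f(w):
        u, v = w[:p], w[p:]
        b = u - v
        r = y - X @ b
        grad_b = -(X.T @ r) / n
        val = 0.5 * float(r @ r) / n + lam * float(np.sum(u) + np.sum(v))
        return val, np.concatenate([grad_b + lam, -grad_b + lam])

    res = minimize(f, np.zeros(2 * p), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p),
                   options={"maxiter": 20_000, "ftol": 1e-16, "gtol": 1e-12})
    b = res.x[:p] - res.x[p:]
    b[np.abs(b) < 1e-10] = 0.0
    return b


def best_subset_ebic(y: np.ndarray, X: np.ndarray, supports, gamma: float):
    """Exhaustive OLS + EBIC search over the given iterable of supports
    (tuples of predictor indices); returns (best support, OLS coefficients)."""
    n, p = X.shape
    best = None
    for supp in supports:
        supp = tuple(sorted(supp))
        k = len(supp)
        if k == 0:
            rss = float(y @ y)
        else:
            Xs = X[:, list(supp)]
            beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            r = y - Xs @ beta
            rss = float(r @ r)
        crit = n * np.log(max(rss, 1e-300) / n) + k * np.log(n) + 2 * gamma * k * np.log(p)
        if best is None or crit < best[0]:
            coef = np.zeros(p)
            if k:
                coef[list(supp)] = beta
            best = (crit, supp, coef)
    return best[1], best[2]


def partial_correlations_from_inverse(S: np.ndarray) -> np.ndarray:
    """Closed-form partial correlations by inverting the correlation matrix."""
    theta = np.linalg.inv(S)
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor
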