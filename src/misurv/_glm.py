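"""Ridge-stabilised regression fits used by the imputation models.

Each fitter returns the coefficient estimate together with the inverse
(penalised) Hessian, so the imputers can draw coefficients from their
approximate asymptotic posterior.  A small ridge (on the standardised
design) keeps fits defined under separation or collinearity, which occur
routinely on small imputation domains.
"""

from __future__ import annotations

import numpy as np

RIDGE = 1e-5
MAX_ITER = 50
TOL = 1e-8


def standardize_design(X: np.ndarray):
    """Center/scale columns and prepend an intercept.

    Returns (Z, transform) where ``transform(Xnew)`` maps new rows onto
    the same standardised basis.  Constant columns are scaled by 1.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0) if X.size else np.zeros(X.shape[1])
    sd = X.std(axis=0) if X.size else np.ones(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)

    def transform(Xn: np.ndarray) -> np.ndarray:
        Xn = np.asarray(Xn, dtype=float)
        Z = (Xn - mu) / sd
        return np.column_stack([np.ones(Z.shape[0]), Z])

    return transform(X), transform


def bayes_linear_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                      ridge: float = RIDGE):
    """Posterior-style draw for a linear model (the PMM workhorse).

    Fits ridge least squares, draws sigma^2 from SSE/chi2(df) and beta
    from N(beta_hat, sigma^2 (X'X + kI)^-1).  Returns (beta_hat,
    beta_draw) on the standardised basis built inside the caller.
    """
    n, p = X.shape
    xtx = X.T @ X + ridge * np.eye(p)
    beta_hat = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / df
    sigma2_draw = float(resid @ resid) / max(rng.chisquare(df), 1e-12)
    cov = sigma2_draw * np.linalg.inv(xtx)
    beta_draw = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return beta_hat, beta_draw, sigma2


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge=RIDGE):
    """Newton/IRLS logistic fit; returns (beta, cov) with cov the inverse
    penalised observed information.

    ``ridge`` may be a scalar or a per-coefficient vector (a diagonal
    Gaussian prior precision); the latter is how the imputers impose a
    weakly-informative prior so the posterior draw stays proper when the
    imputation domain is small or separated.
    """
    n, p = X.shape
    ridge_diag = np.diag(np.broadcast_to(np.asarray(ridge, dtype=float), (p,)).copy())
    beta = np.zeros(p)
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (y - mu) - ridge_diag @ beta
        H = (X * w[:, None]).T @ X + ridge_diag
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < TOL:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = (X * w[:, None]).T @ X + ridge_diag
    return beta, np.linalg.inv(H)


def fit_multinomial(X: np.ndarray, y_codes: np.ndarray, n_classes: int,
                    ridge: float = RIDGE):
    """Newton multinomial-logit fit with class 0 as reference.

    ``y_codes`` are integer classes in [0, n_classes).  Returns
    (B, cov) where B is ((K-1), p) and cov is the inverse penalised
    Hessian of the stacked vec(B) (row-major: class 1 block first).
    """
    n, p = X.shape
    K = n_classes
    nb = K - 1
    B = np.zeros((nb, p))
    Y = np.zeros((n, nb))
    for k in range(1, K):
        Y[:, k - 1] = (y_codes == k).astype(float)
    for _ in range(MAX_ITER):
        eta = X @ B.T                      # (n, K-1)
        eta = np.clip(eta, -30, 30)
        expeta = np.exp(eta)
        denom = 1.0 + expeta.sum(axis=1, keepdims=True)
        P = expeta / denom                 # (n, K-1)
        grad = np.empty(nb * p)
        for k in range(nb):
            grad[k * p:(k + 1) * p] = X.T @ (Y[:, k] - P[:, k]) - ridge * B[k]
        H = np.empty((nb * p, nb * p))
        for k in range(nb):
            for l in range(k, nb):
                w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
                blk = (X * w[:, None]).T @ X
                if k == l:
                    blk = blk + ridge * np.eye(p)
                H[k * p:(k + 1) * p, l * p:(l + 1) * p] = blk
                H[l * p:(l + 1) * p, k * p:(k + 1) * p] = blk.T
        step = np.linalg.solve(H, grad)
        B = B + step.reshape(nb, p)
        if np.max(np.abs(step)) < TOL:
            break
    # final Hessian at the solution
    eta = np.clip(X @ B.T, -30, 30)
    expeta = np.exp(eta)
    P = expeta / (1.0 + expeta.sum(axis=1, keepdims=True))
    H = np.empty((nb * p, nb * p))
    for k in range(nb):
        for l in range(k, nb):
            w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
            blk = (X * w[:, None]).T @ X
            if k == l:
                blk = blk + ridge * np.eye(p)
            H[k * p:(k + 1) * p, l * p:(l + 1) * p] = blk
            H[l * p:(l + 1) * p, k * p:(k + 1) * p] = blk.T
    return B, np.linalg.inv(H)


def multinomial_probs(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Class probabilities (n, K) under a reference-class-0 multinomial logit."""
    eta = np.clip(X @ B.T, -30, 30)
    expeta = np.exp(eta)
    denom = 1.0 + expeta.sum(axis=1, keepdims=True)
    P_rest = expeta / denom
    return np.column_stack([1.0 - P_rest.sum(axis=1), P_rest])
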