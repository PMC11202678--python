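"""Dense profile-REML engine for mixed models with i.i.d. random-effect blocks.

Fits y = X beta + sum_i Z_i u_i + e with u_i ~ N(0, sigma_i^2 I) and
e ~ N(0, sigma_e^2 I).  Writing theta_i = sigma_i^2 / sigma_e^2 and
H(theta) = I + sum_i theta_i Z_i Z_i', the residual variance and the fixed
effects profile out analytically and the restricted log-likelihood becomes a
function of the (at most three) variance ratios only:

    -2 l_R(theta) = (n-p) log(sigma_e_hat^2) + log|H| + log|X' H^-1 X| + const
    sigma_e_hat^2 = y' P y / (n - p).

The ratios are optimized on the log scale by Nelder-Mead (Brent for a single
ratio), which tolerates boundary solutions (a ratio collapsing to ~0).  This
targets the small crossed/nested models of augmented-design trial analysis
(n up to a couple of thousand plots), where a dense Cholesky per evaluation
is cheap and exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

LOG_THETA_LO = -18.0
LOG_THETA_HI = 14.0
_LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedModelFit:
    """REML solution of a variance-components model."""

    beta: np.ndarray
    fixed_names: list
    sigma2: dict  # per random term
    sigma2_e: float
    blups: dict  # per random term: level name -> BLUP
    loglik: float
    converged: bool
    n_obs: int
    perfect_fit: bool = False
    message: str = ""

    def fixed_effects(self) -> pd.Series:
        return pd.Series(self.beta, index=self.fixed_names)


def indicator(codes: pd.Series | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """0/1 indicator matrix and level labels for a factor."""
    codes = pd.Series(np.asarray(codes))
    levels, inv = np.unique(codes.to_numpy(), return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z, levels


def _neg2_reml(log_theta, G_list, X, y, n, p):
    H = np.eye(n)
    for lt, G in zip(log_theta, G_list):
        H += np.exp(lt) * G
    try:
        L = linalg.cholesky(H, lower=True)
    except linalg.LinAlgError:
        return np.inf, None
    logdetH = 2.0 * np.sum(np.log(np.diag(L)))
    Xt = linalg.solve_triangular(L, X, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    XtX = Xt.T @ Xt
    try:
        cf = linalg.cho_factor(XtX)
    except linalg.LinAlgError:
        return np.inf, None
    logdetXtX = 2.0 * np.sum(np.log(np.diag(cf[0])))
    beta = linalg.cho_solve(cf, Xt.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ r)
    if rss <= 0:
        rss = np.finfo(float).tiny
    s2e = rss / (n - p)
    n2 = (n - p) * (np.log(s2e) + _LN2PI + 1.0) + logdetH + logdetXtX
    return n2, (beta, s2e, L, logdetH)


def reml(
    y: np.ndarray,
    X: np.ndarray,
    random_terms: dict,
    tol: float = 1e-8,
    fixed_names=None,
) -> MixedModelFit:
    """REML fit.  ``random_terms`` maps term name -> (Z, level_labels) or Z.

    Raises ``ValueError`` when no random structure is estimable (empty terms)
    or when X has deficient rank.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"b{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    if n <= p:
        raise ValueError("model is not estimable: no residual degrees of freedom")
    names, Zs, labels = [], [], []
    for name, val in random_terms.items():
        if isinstance(val, tuple):
            Z, lab = val
        else:
            Z, lab = val, np.arange(np.asarray(val).shape[1])
        names.append(name)
        Zs.append(np.asarray(Z, dtype=float))
        labels.append(np.asarray(lab))
    if not names:
        raise ValueError("at least one random term is required")

    # Perfect-fit guard: exact-interpolation data make log(sigma_e^2) diverge.
    beta_ols, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    scale = float(np.var(y)) * n + 1e-30
    if rss_ols <= 1e-16 * scale:
        blups = {nm: pd.Series(0.0, index=lab) for nm, lab in zip(names, labels)}
        return MixedModelFit(
            beta=beta_ols,
            fixed_names=list(fixed_names),
            sigma2={nm: 0.0 for nm in names},
            sigma2_e=0.0,
            blups=blups,
            loglik=np.inf,
            converged=True,
            n_obs=n,
            perfect_fit=True,
            message="response lies in the fixed-effect column space",
        )

    G_list = [Z @ Z.T for Z in Zs]
    k = len(G_list)

    def objective(lt):
        lt = np.clip(lt, LOG_THETA_LO, LOG_THETA_HI)
        return _neg2_reml(lt, G_list, X, y, n, p)[0]

    if k == 1:
        res1 = optimize.minimize_scalar(
            lambda t: objective([t]),
            bounds=(LOG_THETA_LO, LOG_THETA_HI),
            method="bounded",
            options={"xatol": 1e-9},
        )
        best_x, best_f, ok = np.array([res1.x]), res1.fun, res1.success
    else:
        # Coarse grid scan picks the basin; one Nelder-Mead polishes it.
        from itertools import product

        start, start_f = np.zeros(k), np.inf
        for pt in product((-4.0, -1.0, 1.5), repeat=k):
            f = objective(np.asarray(pt))
            if f < start_f:
                start, start_f = np.asarray(pt), f
        r = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-6, "maxiter": 2000},
        )
        best_x = np.clip(r.x, LOG_THETA_LO, LOG_THETA_HI)
        best_f, ok = r.fun, r.success
        if start_f < best_f:
            best_x, best_f = start, start_f

    n2, aux = _neg2_reml(best_x, G_list, X, y, n, p)
    beta, s2e, L, _ = aux
    theta = np.exp(best_x)
    # Ratios at the lower optimization bound are boundary zeros.
    theta[best_x <= LOG_THETA_LO + 1e-6] = 0.0
    sigma2 = {nm: float(th * s2e) for nm, th in zip(names, theta)}

    # BLUPs: u_i = theta_i Z_i' H^-1 (y - X beta)
    resid = y - X @ beta
    Hinv_r = linalg.cho_solve((L, True), resid)
    blups = {}
    for nm, Z, lab, th in zip(names, Zs, labels, theta):
        blups[nm] = pd.Series(th * (Z.T @ Hinv_r), index=lab)
    return MixedModelFit(
        beta=beta,
        fixed_names=list(fixed_names),
        sigma2=sigma2,
        sigma2_e=float(s2e),
        blups=blups,
        loglik=float(-0.5 * n2),
        converged=bool(ok),
        n_obs=n,
    )
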