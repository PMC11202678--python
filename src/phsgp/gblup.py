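"""GBLUP with optional QTL-marker fixed effects, fit by profile REML.

Model: y = X beta + Z t + e with t ~ N(0, A sigma_t^2), e ~ N(0, I sigma_e^2)
on line-level adjusted means (Z = I for the training lines).  X is an
intercept plus, in the QTL-weighted variants, one 0/1/2 dosage column per
covariate marker: the full tracked 17-marker panel, the three markers of the
major PHS-resistance locus (*Phs-A1* analogue), or the three FN-per-se loci
(T1RS.1BL / Rht analogues).

Estimation follows the eigendecomposition approach: with A = U D U', rotating
by U' diagonalizes the covariance, and the restricted likelihood profiles
down to a one-dimensional search over the variance ratio
lambda = sigma_t^2 / sigma_e^2, solved by bounded Brent search on log(lambda).
Unphenotyped lines are predicted by the conditional expectation
t_hat_new = A_cross A_train^{-1} t_hat_train, which coincides with solving
the joint mixed-model equations with the new lines' records set missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from phsgp.genotypes import GenotypeMatrix, RelationshipMatrix

LAMBDA_BOUNDS = (1e-6, 1e6)
_LN2PI = float(np.log(2.0 * np.pi))

#: Model variants: name -> how covariate markers are chosen (see ModelSpec).
VARIANTS = ("model1", "model2_qtl17", "model2_phs", "model2_rht")


@dataclass
class ModelSpec:
    """Which fixed-effect covariates enter X besides the intercept."""

    variant: str = "model1"
    covariate_markers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.variant == "model1" and self.covariate_markers:
            raise ValueError("model1 takes no covariate markers")
        if self.variant != "model1" and not self.covariate_markers:
            raise ValueError(f"{self.variant} requires covariate markers")

    @classmethod
    def from_architecture(cls, variant: str, arch) -> "ModelSpec":
        """Convenience constructor mapping a variant to a synthetic architecture's panels."""
        if variant == "model1":
            return cls("model1")
        if variant == "model2_qtl17":
            return cls(variant, list(arch.panel_marker_ids))
        if variant == "model2_phs":
            return cls(variant, list(arch.major_marker_ids)
                       + [m for m, g in arch.qtl_groups.items()
                          if g == "Phs-A1" and m not in arch.major_marker_ids])
        if variant == "model2_rht":
            return cls(variant, list(arch.fn_marker_ids))
        raise ValueError(variant)


@dataclass
class GblupFit:
    """REML solution of the GBLUP model on a training set."""

    beta: np.ndarray
    fixed_names: list
    t_hat: pd.Series
    sigma2_t: float
    sigma2_e: float
    lambda_: float
    loglik: float
    converged: bool
    dropped_columns: list
    n_obs: int

    def variance_ratio(self) -> float:
        """sigma_t^2 / (sigma_t^2 + sigma_e^2): the genomic share of variance."""
        tot = self.sigma2_t + self.sigma2_e
        return self.sigma2_t / tot if tot > 0 else 0.0

    def fixed_effects(self) -> pd.Series:
        return pd.Series(self.beta, index=self.fixed_names)

    def summary_frame(self) -> pd.DataFrame:
        rows = [("sigma2_t", self.sigma2_t), ("sigma2_e", self.sigma2_e),
                ("lambda", self.lambda_), ("loglik", self.loglik),
                ("converged", float(self.converged)), ("n_obs", self.n_obs)]
        return pd.DataFrame(rows, columns=["quantity", "value"])


@dataclass
class Prediction:
    """Predicted values g_hat = X beta + genomic BLUP, components kept separate."""

    fixed_part: pd.Series
    genomic_part: pd.Series

    @property
    def total(self) -> pd.Series:
        return (self.fixed_part + self.genomic_part).rename("gebv")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fixed": self.fixed_part, "genomic": self.genomic_part, "gebv": self.total}
        )


def build_fixed_design(
    spec: ModelSpec, geno: GenotypeMatrix, lines
) -> tuple[np.ndarray, list, list]:
    """Intercept plus covariate-marker dosage columns for the given lines.

    Rank-deficient (aliased) columns are detected by pivoted QR at relative
    tolerance 1e-8 and removed; returns (X, column_names, dropped_names).
    """
    lines = np.atleast_1d(lines)
    if len(lines) == 0:
        raise ValueError("no lines given")
    X = np.ones((len(lines), 1))
    names = ["intercept"]
    if spec.covariate_markers:
        sub = geno.subset(lines=lines, markers=spec.covariate_markers)
        if np.isnan(sub.dosages).any():
            raise ValueError("covariate markers contain missing calls; impute first")
        X = np.hstack([X, sub.dosages])
        names = names + [str(m) for m in spec.covariate_markers]
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = 1e-8 * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
    return X[:, keep], [names[j] for j in keep], dropped


def _profile_neg2_reml(log_lam, d, Xt, yt, n, p):
    """-2 restricted log-likelihood profiled over beta and sigma_e^2."""
    lam = np.exp(log_lam)
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    try:
        cf = linalg.cho_factor(XtWX)
    except linalg.LinAlgError:
        return np.inf, None
    beta = linalg.cho_solve(cf, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (r / w))
    if rss <= 0:
        rss = np.finfo(float).tiny
    s2e = rss / (n - p)
    n2 = (
        (n - p) * (np.log(s2e) + _LN2PI + 1.0)
        + float(np.sum(np.log(w)))
        + 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    )
    return n2, (beta, s2e, w, r)


def reml_fit(
    y,
    X,
    A: RelationshipMatrix | np.ndarray,
    lines=None,
    fixed_names=None,
    lambda_bounds=LAMBDA_BOUNDS,
    ridge: float = 1e-6,
) -> GblupFit:
    """Fit GBLUP by profile REML over lambda = sigma_t^2 / sigma_e^2.

    ``y`` may be a pandas Series indexed by line (then ``A`` rows are matched
    by id) or an array aligned with ``A``.  A ridge of ``ridge`` is added to
    A's eigenvalues only when the smallest falls below 1e-8, which keeps the
    rotated weights strictly positive without changing a well-conditioned A.
    """
    if isinstance(y, pd.Series):
        lines = y.index.to_numpy() if lines is None else np.atleast_1d(lines)
        yv = y.loc[lines].to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float).ravel()
        if lines is None:
            lines = np.arange(len(yv))
    if isinstance(A, RelationshipMatrix):
        Av = A.submatrix(lines)
    else:
        Av = np.asarray(A, dtype=float)
    n = len(yv)
    if Av.shape != (n, n):
        raise ValueError("A block does not match the number of observations")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if p == 0 or np.linalg.matrix_rank(X) < p:
        raise ValueError("X must have full column rank >= 1")
    if fixed_names is None:
        fixed_names = [f"b{j}" for j in range(p)]

    d, U = linalg.eigh(Av)
    if d[0] < 1e-8:
        d = d + ridge
    Xt = U.T @ X
    yt = U.T @ yv
    lo, hi = np.log(lambda_bounds[0]), np.log(lambda_bounds[1])
    res = optimize.minimize_scalar(
        lambda ll: _profile_neg2_reml(ll, d, Xt, yt, n, p)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    n2, aux = _profile_neg2_reml(res.x, d, Xt, yt, n, p)
    beta, s2e, w, r = aux
    lam = float(np.exp(res.x))
    # BLUP in rotated space: t~ = lam*d/(lam*d+1) * residual~
    t_rot = (lam * d / w) * r
    t_hat = pd.Series(U @ t_rot, index=lines, name="t_hat")
    return GblupFit(
        beta=beta,
        fixed_names=list(fixed_names),
        t_hat=t_hat,
        sigma2_t=float(lam * s2e),
        sigma2_e=float(s2e),
        lambda_=lam,
        loglik=float(-0.5 * n2),
        converged=bool(res.success),
        dropped_columns=[],
        n_obs=n,
    )


def profile_loglik_grid(y, X, A, log10_lambda_grid, lines=None, ridge: float = 1e-6):
    """Restricted log-likelihood on a grid of log10(lambda) values.

    Independent oracle surface for checking that the optimizer's maximum
    dominates every grid point.
    """
    if isinstance(y, pd.Series):
        lines = y.index.to_numpy() if lines is None else np.atleast_1d(lines)
        yv = y.loc[lines].to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float).ravel()
    Av = A.submatrix(lines) if isinstance(A, RelationshipMatrix) else np.asarray(A, float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    d, U = linalg.eigh(Av)
    if d[0] < 1e-8:
        d = d + ridge
    Xt, yt = U.T @ X, U.T @ yv
    out = []
    for l10 in np.asarray(log10_lambda_grid, dtype=float):
        n2, _ = _profile_neg2_reml(l10 * np.log(10.0), d, Xt, yt, n, p)
        out.append(-0.5 * n2)
    return np.asarray(out)


def predict_gebv(
    fit: GblupFit,
    A_cross: np.ndarray,
    A_train: np.ndarray,
    X_target: np.ndarray,
    target_lines=None,
    ridge: float = 1e-6,
) -> Prediction:
    """Predict unphenotyped lines: g_hat = X_target beta + A_cross A_train^-1 t_hat.

    ``A_cross`` has target lines as rows and training lines as columns, in the
    order of ``fit.t_hat``.  A singular training kinship receives the standard
    logged ridge on its diagonal.
    """
    A_cross = np.atleast_2d(np.asarray(A_cross, dtype=float))
    A_train = np.asarray(A_train, dtype=float)
    X_target = np.atleast_2d(np.asarray(X_target, dtype=float))
    n_t, n_tr = A_cross.shape
    if A_train.shape != (n_tr, n_tr) or len(fit.t_hat) != n_tr:
        raise ValueError("kinship blocks do not conform with the fit")
    if X_target.shape != (n_t, len(fit.beta)):
        raise ValueError("X_target must match (targets, fitted fixed effects)")
    if target_lines is None:
        target_lines = np.arange(n_t)
    ev_min = float(linalg.eigh(A_train, eigvals_only=True, subset_by_index=[0, 0])[0])
    if ev_min < 1e-8:
        A_train = A_train + ridge * np.eye(n_tr)
    genomic = A_cross @ linalg.solve(A_train, fit.t_hat.to_numpy(), assume_a="pos")
    fixed = X_target @ fit.beta
    return Prediction(
        fixed_part=pd.Series(fixed, index=target_lines, name="fixed"),
        genomic_part=pd.Series(genomic, index=target_lines, name="genomic"),
    )
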