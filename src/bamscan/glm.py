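"""Maximum-likelihood logistic regression, likelihood ratios, collinearity.

A Newton (IRLS) fitter specialised for the sampler's access pattern: the
chain revisits the same inclusion vectors constantly, so fits are memoized
by sorted index tuple in :class:`FitCache` — the dominant cost lever.
Collinear designs are detected up front via SVD rank and given zero
likelihood, which the sampler and the enumeration oracle translate into
log posterior odds of -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .priors import PriorSpec, inclusion_vector, log_posterior_odds_model

__all__ = [
    "Dataset",
    "ModelFit",
    "FitCache",
    "fit_logistic",
    "log_likelihood_ratio",
    "collinearity_check",
]

RANK_TOL = 1e-8          # relative condition threshold for rank deficiency
CONV_TOL = 1e-10         # relative log-likelihood change declaring convergence
MAX_ITER = 50


@dataclass
class Dataset:
    """Observations x variables design plus binary outcome.

    ``X`` must be fully numeric with no missing values (imputation and
    encoding happen upstream); ``y`` must contain both classes.
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; impute upstream")
        uniq = np.unique(self.y)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ValueError("y must be coded 0/1")
        if uniq.size < 2:
            raise ValueError("y must contain both outcome classes")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names length must equal number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def nu(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ModelFit:
    """Result of one maximum-likelihood fit.

    ``beta``/``cov`` cover the intercept (position 0) followed by the
    included variables in sorted index order, so their dimension is |s|+1.
    """

    s: tuple[int, ...]
    loglik: float
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    collinear: bool

    @property
    def size(self) -> int:
        return len(self.s)


def collinearity_check(
    data: Dataset, s: Sequence[int], tol: float = RANK_TOL
) -> bool:
    """True when the included design submatrix (with intercept) is rank-deficient.

    Rank is judged by SVD with a relative tolerance ``tol`` on the largest
    singular value, so byte-identical duplicates, complementary indicator
    pairs (x and 1-x sum to the intercept) and any other exact linear
    dependence all register.
    """
    s = inclusion_vector(s, data.nu)
    if not s:
        return False
    A = np.column_stack([np.ones(data.n), data.X[:, s]])
    sv = np.linalg.svd(A, compute_uv=False)
    return bool(sv[-1] <= tol * sv[0])


def _null_fit(data: Dataset) -> ModelFit:
    # closed form: p_hat = mean(y)
    k = float(data.y.sum())
    n = data.n
    p = k / n
    loglik = k * math.log(p) + (n - k) * math.log1p(-p)
    beta = np.array([math.log(p / (1.0 - p))])
    cov = np.array([[1.0 / (n * p * (1.0 - p))]])
    return ModelFit((), loglik, beta, cov, True, False)


def fit_logistic(
    data: Dataset,
    s: Sequence[int],
    *,
    tol: float = CONV_TOL,
    max_iter: int = MAX_ITER,
) -> ModelFit:
    """Newton/IRLS maximum-likelihood logistic fit with intercept.

    Deterministic given (data, s).  A rank-deficient design returns a fit
    flagged ``collinear`` (zero likelihood downstream); failure to converge
    within ``max_iter`` iterations (e.g. perfect separation on a rare binary
    indicator) returns ``converged=False``, which the sampler treats as a
    rejected proposal.
    """
    s = inclusion_vector(s, data.nu)
    if not s:
        return _null_fit(data)
    if collinearity_check(data, s):
        k = len(s) + 1
        return ModelFit(s, -math.inf, np.full(k, np.nan), np.full((k, k), np.nan),
                        False, True)

    y = data.y
    A = np.column_stack([np.ones(data.n), data.X[:, s]])
    beta = np.zeros(A.shape[1])
    p_bar = y.mean()
    beta[0] = math.log(p_bar / (1.0 - p_bar))

    def loglik_of(eta: np.ndarray) -> float:
        # sum y*eta - log(1 + exp(eta)), stable for large |eta|
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    eta = A @ beta
    ll = loglik_of(eta)
    converged = False
    H = None
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = A.T @ (y - p)
        H = A.T @ (A * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # halve the step until the log-likelihood does not decrease
        new_beta = beta + step
        new_eta = A @ new_beta
        new_ll = loglik_of(new_eta)
        shrink = 0
        while new_ll < ll and shrink < 30:
            step *= 0.5
            new_beta = beta + step
            new_eta = A @ new_beta
            new_ll = loglik_of(new_eta)
            shrink += 1
        beta, eta = new_beta, new_eta
        if abs(new_ll - ll) <= tol * (abs(ll) + 1e-300):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    if converged and H is not None:
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        H = A.T @ (A * w[:, None])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((A.shape[1], A.shape[1]), np.nan)
            converged = False
    else:
        cov = np.full((A.shape[1], A.shape[1]), np.nan)
    return ModelFit(s, ll, beta, cov, converged, False)


def log_likelihood_ratio(fit: ModelFit, null_fit: ModelFit) -> float:
    """log R_s = loglik(s) - loglik(null); nonnegative up to convergence slack."""
    if null_fit.size != 0:
        raise ValueError("null_fit must be the intercept-only model")
    if fit.collinear:
        return -math.inf
    lr = fit.loglik - null_fit.loglik
    if lr < -1e-6:
        raise ValueError(
            f"negative log likelihood ratio ({lr:.3g}): fit did not converge"
        )
    return max(lr, 0.0)


class FitCache:
    """Memoized fits and posterior odds for one dataset.

    Keyed by sorted index tuple; repeated queries return bit-identical
    results.  The null fit is computed once in closed form.
    """

    def __init__(self, data: Dataset):
        self.data = data
        self.null = _null_fit(data)
        self._fits: dict[tuple[int, ...], ModelFit] = {(): self.null}
        self.n_fits = 0

    def fit(self, s: Sequence[int]) -> ModelFit:
        key = inclusion_vector(s, self.data.nu)
        hit = self._fits.get(key)
        if hit is None:
            hit = fit_logistic(self.data, key)
            self._fits[key] = hit
            self.n_fits += 1
        return hit

    def log_po(self, s: Sequence[int], prior: PriorSpec) -> float:
        """Log posterior odds of model s vs the null; -inf for collinear or
        non-converged (unavailable) models."""
        f = self.fit(s)
        if f.collinear or not f.converged:
            return -math.inf
        return log_posterior_odds_model(
            f.s, log_likelihood_ratio(f, self.null), prior
        )
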