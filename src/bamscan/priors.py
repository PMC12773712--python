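"""Prior specification and closed-form posterior-odds machinery.

The model space is the set of 2**nu logistic regressions indexed by an
inclusion vector ``s`` (which variables have nonzero coefficients).  Each
variable enters independently with prior odds ``mu``; nonzero coefficients
carry a unit-information Normal prior with precision ``h``.  Under Johnson's
large-sample approximation the posterior odds of model ``s`` against the
intercept-only null are

    PO_s  ~=  [ mu * sqrt(h / (n + h)) ]**|s|  *  R_s**(n / (n + h))

where ``R_s`` is the ratio of maximized likelihoods of model ``s`` versus the
null.  All arithmetic here is carried out in natural-log space: at biobank
scale (|s| in the tens, n ~ 1e5) linear-scale odds overflow doubles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "PriorSpec",
    "GroupQuery",
    "inclusion_vector",
    "calibration_constant",
    "expected_model_size",
    "log_posterior_odds_model",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the model space.

    Parameters
    ----------
    mu : float
        Prior odds that any one regression coefficient is nonzero
        (dimensionless, > 0; may be 0 only as a degenerate null prior).
    h : float
        Prior precision of nonzero coefficients relative to the information
        in one observation (h = 1 is the unit-information prior).
    nu : int
        Number of candidate variables.
    n : int
        Number of observations.
    """

    mu: float
    h: float
    nu: int
    n: int

    def __post_init__(self) -> None:
        for name in ("mu", "h"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h!r}")
        if self.nu < 1:
            raise ValueError(f"nu must be >= 1, got {self.nu!r}")
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n!r}")

    @property
    def log_penalty(self) -> float:
        """Per-variable log inclusion penalty: log mu + 0.5*(log h - log(n+h))."""
        if self.mu == 0:
            return -math.inf
        return math.log(self.mu) + 0.5 * (math.log(self.h) - math.log(self.n + self.h))

    @property
    def shrinkage(self) -> float:
        """Likelihood-ratio exponent n/(n+h); also the coefficient shrinkage factor."""
        return self.n / (self.n + self.h)

    @property
    def inclusion_probability(self) -> float:
        """Prior probability mu/(1+mu) that a single variable is included."""
        return self.mu / (1.0 + self.mu)


@dataclass(frozen=True)
class GroupQuery:
    """A joint null hypothesis: all variables in ``tested`` have zero coefficients.

    The alternative is that at least one of them is included.  A singleton
    group is an ordinary single-variable test.
    """

    tested: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        t = tuple(sorted(set(int(i) for i in self.tested)))
        if not t:
            raise ValueError("tested set must be nonempty")
        if t[0] < 0:
            raise ValueError("variable indices must be nonnegative")
        object.__setattr__(self, "tested", t)

    def validate(self, nu: int) -> None:
        if self.tested[-1] >= nu:
            raise ValueError(f"index {self.tested[-1]} out of range for nu={nu}")


def inclusion_vector(included: Iterable[int], nu: int) -> tuple[int, ...]:
    """Normalize an inclusion vector to a sorted tuple of unique indices in range."""
    s = tuple(sorted(set(int(i) for i in included)))
    if s and (s[0] < 0 or s[-1] >= nu):
        raise ValueError(f"indices {s} out of range for nu={nu}")
    return s


def calibration_constant(prior: PriorSpec) -> float:
    """Log of the constant c = nu * mu * sqrt(h / (n + h)).

    Dividing posterior odds by c yields the chi-squared(1)-calibrated
    model-averaged deviance: both the adjusted P-value and the FWER
    corresponding to an odds threshold are upper-tail chi-squared
    probabilities at 2*(log PO - log c).
    """
    if prior.mu == 0:
        raise ValueError("calibration constant undefined for mu = 0")
    return (
        math.log(prior.nu * prior.mu)
        + 0.5 * (math.log(prior.h) - math.log(prior.n + prior.h))
    )


def expected_model_size(prior: PriorSpec) -> float:
    """Prior mean number of included variables, nu * mu / (1 + mu)."""
    return prior.nu * prior.inclusion_probability


def log_posterior_odds_model(
    s: Sequence[int],
    log_lr: float,
    prior: PriorSpec,
    *,
    collinear: bool = False,
) -> float:
    """Log posterior odds of model ``s`` against the intercept-only null.

    Parameters
    ----------
    s : sequence of int
        Included variable indices (the intercept is always present and never
        counted).
    log_lr : float
        log R_s: maximized log-likelihood of model ``s`` minus that of the
        null model, fitted on the same data.
    prior : PriorSpec
    collinear : bool
        Models declared collinear carry zero likelihood: log odds -inf.

    Returns
    -------
    float
        |s| * [log mu + (log h - log(n+h))/2] + n/(n+h) * log_lr;
        exactly 0.0 for the empty model.
    """
    if collinear:
        return -math.inf
    k = len(s)
    if k == 0:
        return 0.0
    if not math.isfinite(log_lr):
        raise ValueError(f"log likelihood ratio must be finite, got {log_lr!r}")
    return k * prior.log_penalty + prior.shrinkage * log_lr
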