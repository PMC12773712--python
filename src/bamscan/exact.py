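"""Exhaustive-enumeration oracle over the full model space.

For nu up to a desk-scale cap this computes the exact posterior over all
2**nu models from the closed-form odds, giving exact marginal inclusion
probabilities and exact group odds.  It is the reference the MCMC sampler
is validated against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .glm import Dataset, FitCache
from .priors import GroupQuery, PriorSpec

__all__ = ["ExactPosterior", "enumerate_posterior", "group_odds_exact"]

DEFAULT_MAX_NU = 15


@dataclass
class ExactPosterior:
    """Normalized posterior over all non-collinear models."""

    models: list[tuple[int, ...]]
    log_prob: np.ndarray          # normalized log posterior probabilities
    marginal: np.ndarray          # per-variable inclusion probabilities
    nu: int
    n_collinear: int

    def prob(self, s: tuple[int, ...]) -> float:
        try:
            i = self.models.index(tuple(sorted(s)))
        except ValueError:
            return 0.0
        return float(np.exp(self.log_prob[i]))


def enumerate_posterior(
    data: Dataset,
    prior: PriorSpec,
    max_nu: int = DEFAULT_MAX_NU,
    cache: FitCache | None = None,
) -> ExactPosterior:
    """Exact model posterior by brute force over all 2**nu inclusion vectors.

    Collinear (and non-converged) models carry zero likelihood and are
    excluded before normalization.  Refuses nu > max_nu: the point is a
    desk-scale oracle, not a production path.
    """
    nu = data.nu
    if nu > max_nu:
        raise ValueError(f"nu={nu} exceeds enumeration cap max_nu={max_nu}")
    if cache is None:
        cache = FitCache(data)
    models: list[tuple[int, ...]] = []
    log_odds: list[float] = []
    n_collinear = 0
    for k in range(nu + 1):
        for s in itertools.combinations(range(nu), k):
            lo = cache.log_po(s, prior)
            if math.isinf(lo):
                n_collinear += 1
                continue
            models.append(s)
            log_odds.append(lo)
    lo_arr = np.asarray(log_odds)
    log_prob = lo_arr - logsumexp(lo_arr)
    marginal = np.zeros(nu)
    for s, lp in zip(models, log_prob):
        p = math.exp(lp)
        for j in s:
            marginal[j] += p
    return ExactPosterior(models, log_prob, marginal, nu, n_collinear)


def group_odds_exact(posterior: ExactPosterior, q: GroupQuery) -> float:
    """Exact log posterior odds that >=1 tested variable is included.

    log of the posterior mass over models including any tested variable
    minus log of the mass over models including none.  Returns +/-inf when
    one side carries zero mass (a hard bound, not an estimate).
    """
    q.validate(posterior.nu)
    tested = set(q.tested)
    in_alt = np.fromiter(
        (bool(tested.intersection(s)) for s in posterior.models),
        dtype=bool,
        count=len(posterior.models),
    )
    if not in_alt.any():
        return -math.inf
    if in_alt.all():
        return math.inf
    return float(
        logsumexp(posterior.log_prob[in_alt])
        - logsumexp(posterior.log_prob[~in_alt])
    )
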