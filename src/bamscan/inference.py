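"""From pooled samples to reported quantities.

Everything downstream of the sampler lives here: posterior inclusion
probabilities with Monte-Carlo standard errors, the chi-squared
interconversion between posterior odds and multiplicity-adjusted P-values,
the simultaneous Bayesian-FDR / frequentist-FWER calibration of an odds
threshold tau, conditional effect summaries simulated from the stored
draws, and the ranked significance table.

The core identity: the statistic 2*log(PO / c), with calibration constant
c = nu*mu*sqrt(h/(n+h)), is asymptotically chi-squared with 1 df under the
null, so

    p*    = Pr(chi2_1 > 2*log(PO / c))        (adjusted P-value)
    alpha = Pr(chi2_1 > 2*log(tau / c))       (FWER of threshold tau)
    FDR  <= 1 / (1 + tau)

share one code path.  Chi-squared tails are computed via the log survival
function so -log10 p* far beyond double-precision linear tails remains
representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .glm import Dataset, FitCache
from .priors import GroupQuery, PriorSpec, calibration_constant
from .sampler import SampleStore, mcse

__all__ = [
    "SignificanceRecord",
    "ThresholdPair",
    "inclusion_probability",
    "log_odds_from_pp",
    "po_to_pstar",
    "neglog10_pstar",
    "fwer_from_tau",
    "fdr_bound",
    "threshold_pair",
    "conditional_effect_summary",
    "make_records",
    "significance_report",
    "manhattan_table",
]

NS_CUTOFF = 0.02  # adjusted P-values above this are reported as n.s.


@dataclass(frozen=True)
class SignificanceRecord:
    """One row of the results table: a variable or group test."""

    label: str
    pp: float                    # posterior probability of inclusion, percent
    log10_po: float              # log10 posterior odds
    pstar: float                 # adjusted P-value
    neglog10_pstar: float
    effect: float | None = None      # posterior mean coefficient when included
    effect_se: float | None = None   # posterior SD when included
    pp_mcse: float | None = None     # Monte-Carlo SE of pp (percent)
    is_bound: bool = False       # pp saturated at 0/100%: odds are a bound
    members: tuple[int, ...] = ()

    @property
    def is_ns(self) -> bool:
        return self.pstar > NS_CUTOFF


@dataclass(frozen=True)
class ThresholdPair:
    """Joint calibration of one posterior-odds threshold."""

    tau: float
    fdr_bound: float
    alpha: float


# ---------------------------------------------------------------------------
# sample summaries


def inclusion_probability(
    store: SampleStore, q: GroupQuery | Iterable[int]
) -> tuple[float, float]:
    """Posterior probability (fraction) that >=1 tested variable is included.

    Returns (pp, mcse), both on the 0-1 scale, pooled over chains with the
    Monte-Carlo standard error taken across chains.
    """
    tested = q.tested if isinstance(q, GroupQuery) else tuple(q)
    pp = store.pooled_inclusion(tested)
    se = mcse(store, tested) if store.n_chains >= 2 else float("nan")
    return pp, se


def log_odds_from_pp(pp: float, n_draws: int | None = None) -> tuple[float, bool]:
    """Log posterior odds pp/(1-pp) with a pseudo-count bound at saturation.

    A pp estimated as exactly 0 or 1 from N pooled draws is a bound, not an
    estimate; one pseudo-count gives odds N/1 (or 1/N) and the flag marks
    the value as a bound for reporting (e.g. "> x").
    """
    if not 0.0 <= pp <= 1.0:
        raise ValueError("pp must lie in [0, 1]")
    if pp in (0.0, 1.0):
        if n_draws is None:
            return (math.inf if pp == 1.0 else -math.inf), True
        return (math.log(n_draws) if pp == 1.0 else -math.log(n_draws)), True
    return math.log(pp) - math.log1p(-pp), False


# ---------------------------------------------------------------------------
# chi-squared interconversion (shared code path)


def _chi2_tail(stat: float) -> tuple[float, float]:
    """(p, -log10 p) of the upper chi2_1 tail, via the log survival function."""
    if stat <= 0:
        return 1.0, 0.0
    logsf = chi2.logsf(stat, df=1)
    return float(np.exp(logsf)), float(-logsf / math.log(10.0))


def po_to_pstar(log_po: float, prior: PriorSpec) -> float:
    """Adjusted P-value from log posterior odds: Pr(chi2_1 > 2*(log PO - log c)).

    Odds at or below the calibration constant map to p* = 1.  The
    adjustment is simultaneous over all 2**nu - 1 group hypotheses; the
    reporting layer treats p* > 0.02 as not significant, where the
    chi-squared approximation stops being conservative.
    """
    if math.isnan(log_po):
        raise ValueError("log_po is NaN")
    if log_po == -math.inf:
        return 1.0
    stat = 2.0 * (log_po - calibration_constant(prior))
    return _chi2_tail(stat)[0]


def neglog10_pstar(log_po: float, prior: PriorSpec) -> float:
    """-log10 of the adjusted P-value, exact in log space for extreme odds."""
    if log_po == -math.inf:
        return 0.0
    if log_po == math.inf:
        return math.inf
    stat = 2.0 * (log_po - calibration_constant(prior))
    return _chi2_tail(stat)[1]


def fwer_from_tau(tau: float, prior: PriorSpec) -> float:
    """Asymptotic familywise error rate of rejecting at posterior odds > tau.

    Identical code path to :func:`po_to_pstar` with PO := tau; a threshold
    at or below the calibration constant gives alpha = 1.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return po_to_pstar(math.log(tau), prior)


def fdr_bound(tau: float) -> float:
    """Bayesian false discovery rate bound 1/(1+tau) at odds threshold tau."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 / (1.0 + tau)


def threshold_pair(tau: float, prior: PriorSpec) -> ThresholdPair:
    return ThresholdPair(tau, fdr_bound(tau), fwer_from_tau(tau, prior))


# ---------------------------------------------------------------------------
# conditional effects


def conditional_effect_summary(
    store: SampleStore,
    data: Dataset,
    variable: int,
    prior: PriorSpec,
    *,
    cache: FitCache | None = None,
    max_draws: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Posterior mean and SD of a coefficient conditional on inclusion.

    For every stored draw whose model includes the variable, one
    coefficient value is simulated from the conditional Normal centred at
    the shrunken MLE n/(n+h)*beta_hat with variance n/(n+h)*var_hat from
    that model's fit; the summary pools between-model and within-model
    uncertainty.  ``max_draws`` caps the number of simulated values by
    uniform thinning.  Raises if the variable is never included.
    """
    if cache is None:
        cache = FitCache(data)
    counts = store.model_counts()
    rel = [(s, c) for s, c in counts.items() if variable in s]
    if not rel:
        raise ValueError(f"variable {variable} is never included in the draws")
    total = sum(c for _, c in rel)
    thin = 1.0 if max_draws is None or total <= max_draws else max_draws / total
    rng = np.random.default_rng(seed)
    shrink = prior.shrinkage
    sims: list[np.ndarray] = []
    for s, c in rel:
        m = c if thin == 1.0 else rng.binomial(c, thin)
        if m == 0:
            continue
        f = cache.fit(s)
        if f.collinear or not f.converged:
            continue
        j = s.index(variable) + 1  # position after the intercept
        mean = shrink * f.beta[j]
        sd = math.sqrt(shrink * f.cov[j, j])
        sims.append(rng.normal(mean, sd, size=m))
    draws = np.concatenate(sims)
    return float(draws.mean()), float(draws.std(ddof=1)) if draws.size > 1 else 0.0


# ---------------------------------------------------------------------------
# reporting


def make_records(
    store: SampleStore,
    data: Dataset,
    prior: PriorSpec,
    queries: Sequence[GroupQuery] | None = None,
    *,
    cache: FitCache | None = None,
    effects: bool = True,
    effect_seed: int = 0,
    max_effect_draws: int = 50000,
) -> list[SignificanceRecord]:
    """Build significance records for every variable (default) or for the
    given group queries."""
    if cache is None:
        cache = FitCache(data)
    if queries is None:
        queries = [GroupQuery((j,), data.names[j]) for j in range(data.nu)]
    n_draws = store.n_total
    records = []
    for q in queries:
        pp, se = inclusion_probability(store, q)
        log_po, bound = log_odds_from_pp(pp, n_draws)
        eff = eff_se = None
        if effects and len(q.tested) == 1 and pp > 0:
            eff, eff_se = conditional_effect_summary(
                store, data, q.tested[0], prior,
                cache=cache, max_draws=max_effect_draws, seed=effect_seed,
            )
        records.append(
            SignificanceRecord(
                label=q.label or ",".join(str(i) for i in q.tested),
                pp=100.0 * pp,
                log10_po=log_po / math.log(10.0),
                pstar=po_to_pstar(log_po, prior),
                neglog10_pstar=neglog10_pstar(log_po, prior),
                effect=eff,
                effect_se=eff_se,
                pp_mcse=100.0 * se if se == se else None,
                is_bound=bound,
                members=q.tested,
            )
        )
    return records


def significance_report(
    records: Sequence[SignificanceRecord], tau: float
) -> pd.DataFrame:
    """Ranked results table in the style of a model-averaged scan report.

    Sorted by posterior probability; ``significant`` marks PO > tau;
    display columns render pp to 1 decimal, -log10 p* to 2 decimals,
    saturated odds as explicit bounds (">"/"<") and p* above 0.02 as "-".
    Full-precision machine columns are retained alongside.
    """
    log10_tau = math.log10(tau)
    rows = []
    for r in sorted(records, key=lambda r: r.pp, reverse=True):
        sig = r.log10_po > log10_tau if not math.isnan(r.log10_po) else False
        prefix = (">" if r.pp >= 50 else "<") if r.is_bound else ""
        disp_p = "-" if r.is_ns else f"{prefix}{r.neglog10_pstar:.2f}"
        rows.append(
            {
                "label": r.label,
                "pp_pct": round(r.pp, 1),
                "neglog10_pstar_display": disp_p,
                "effect": None if r.effect is None else round(r.effect, 3),
                "effect_se": None if r.effect_se is None else round(r.effect_se, 3),
                "significant": bool(sig),
                "is_bound": r.is_bound,
                "pp_full": r.pp,
                "log10_po": r.log10_po,
                "pstar": r.pstar,
                "neglog10_pstar": r.neglog10_pstar,
                "pp_mcse": r.pp_mcse,
                "members": ";".join(map(str, r.members)),
            }
        )
    return pd.DataFrame(rows)


def manhattan_table(
    records: Sequence[SignificanceRecord],
    cluster_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Plot-ready table: one row per variable with both evidence scales."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "label": r.label,
                "log10_po": r.log10_po,
                "neglog10_pstar": r.neglog10_pstar,
                "cluster": cluster_ids[i] if cluster_ids is not None else -1,
            }
        )
    return pd.DataFrame(rows)
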