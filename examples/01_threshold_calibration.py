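"""Joint Bayesian-frequentist calibration of a posterior-odds threshold.

Under the study prior (mu = 0.0053, h = 1, nu = 1,912 variables,
n = 201,917 participants), a single posterior-odds threshold tau
simultaneously bounds the Bayesian false discovery rate at 1/(1+tau) and
the frequentist familywise error rate via the chi-squared transform of
2*log(tau/c), c = nu*mu*sqrt(h/(n+h)).  The same transform turns any
variable's posterior inclusion probability into a multiplicity-adjusted
P-value, so the Bayesian and frequentist rejection rules coincide.
"""

import math

from bamscan import (
    PriorSpec, calibration_constant, expected_model_size, fdr_bound,
    fwer_from_tau, log_odds_from_pp, neglog10_pstar,
)

prior = PriorSpec(mu=0.0053, h=1.0, nu=1912, n=201917)

print(f"calibration constant c = {math.exp(calibration_constant(prior)):.5f}")
print(f"prior expected model size = {expected_model_size(prior):.2f} variables")

for tau in (3.0, 10.0, 30.0):
    alpha = fwer_from_tau(tau, prior)
    print(
        f"tau = {tau:>4.0f}:  FDR <= {fdr_bound(tau):.3f},  "
        f"FWER alpha = {alpha:.2e}  (-log10 = {-math.log10(alpha):.2f})"
    )

print("\nposterior probability -> adjusted P-value:")
for pp in (40.8, 66.1, 89.0, 99.0):
    log_po, _ = log_odds_from_pp(pp / 100.0)
    print(f"  PP = {pp:5.1f}%  ->  -log10 P* = {neglog10_pstar(log_po, prior):.2f}")

# A variable is exposome-wide significant at tau = 10 exactly when
# PP > 90.9% (odds 10), equivalently when P* < alpha = 4.8e-4: one
# threshold, two interpretations.
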