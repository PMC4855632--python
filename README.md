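# devplan

Design and comparison of phase II drug development plans with a binary
(tumour-response) endpoint: should a programme begin with a single-arm
trial, or go straight to a randomised two-arm trial?

`devplan` is aimed at trial statisticians planning a phase II programme as
a whole rather than one trial at a time. It composes six canonical
development plans, calibrates them to common plan-wide error rates, and
compares them by power, expected sample size and power per patient across
every possible pair of true response rates — then weighs the regions where
each plan class wins under "sceptic" and "enthusiast" reference priors.

## The plans and the model

Let `pE` and `pC` be the true response rates on the experimental and
control arms, `p0` the null (uninteresting) rate and `p1` the target rate.
Single-arm trials test `H0S: pE <= p0` against `H1S: pE >= p1`; randomised
trials test `H0R: pE - pC <= 0` against `H1R: pE - pC >= p1 - p0`.

* **DP1** — Simon's two-stage `H0S`-optimal single-arm trial, then (only if
  `H0S` is rejected) a single-stage randomised trial.
* **DP2** — as DP1 with early stopping for efficacy in the single-arm stage.
* **DP3** — a single-stage randomised trial alone.
* **DP4** — a three-look group-sequential randomised trial, equally spaced
  looks, go/no-go stopping at every look.
* **DP5** — a group-sequential trial with futility-only looks timed at the
  Simon stage sizes of DP1, plus a final go/no-go analysis.
* **DP6** — a group-sequential trial with one futility-only look at the
  Simon total, then two further equally spaced go/no-go looks.

Every plan is calibrated to plan-wide one-sided errors `alpha` (at the
global null `pC = pE = p0`) and `beta` (at the global alternative
`pC = p0, pE = p1`); the two-trial plans split them as
`alpha_s = alpha_r = sqrt(alpha)` and `beta_s = beta_r = 1 - sqrt(1-beta)`.
Single-arm calculations are exact binomial sums; randomised designs use the
normal approximation to the difference of two proportions, with
group-sequential boundaries from Lan–DeMets error spending under the
rho-family spending function `f(t) = err * t^rho` (binding futility,
boundary crossing probabilities by recursive numerical integration of the
canonical joint normal distribution).

Plans are ranked at each `(pC, pE)` under four optimality criteria —
OC1 `min E(N)`, OC2 `min E(N)` subject to power `> 1 - beta`,
OC3 `max P/E(N)`, OC4 the floored version of OC3 — and beta reference
priors on `pE` (sceptic: mode `p0`, 10% mass above `p1`; enthusiast: mode
`p1`, 10% mass below `p0`) convert the winner maps into probabilities that
a single-arm-incorporating plan, a randomised-only plan, or no plan at all
should be used.

## Worked example

The scenario of a completed non-small-cell lung cancer programme:
`p0 = 0.15`, `p1 = 0.30`, `alpha = 0.0025`, `beta = 0.36` (so DP1–DP2 run
each trial at `alpha 0.05 / beta 0.2`).

```python
from devplan import GlobalErrorSpec, build_plans, plan_summary_table

plans = build_plans(0.15, 0.30, GlobalErrorSpec(alpha=0.0025, beta=0.36))
print(plan_summary_table(plans, 0.15, 0.30, observed=(0.15, 0.41)))
```

prints (sample sizes in patients, `h0`/`h1`/`o` = global null, global
alternative, observed rates `pE = 0.41`):

```
        simon_design   n1     n2     n3  max_n  en_h0    p_h0  en_h1    p_h1   en_o     p_o
plan
DP1       3/19 12/55  186    NaN    NaN    241   39.2  0.0024  199.1  0.6413  236.6  0.9735
DP2   (3 7)/19 12/55  186    NaN    NaN    241   39.3  0.0024  192.7  0.6419  216.9  0.9736
DP3              N/A  302    NaN    NaN    302  302.0  0.0025  302.0  0.6427  302.0  0.9929
DP4              N/A  120  240.0  360.0    360  146.7  0.0025  252.7  0.6479  176.7  0.9899
DP5              N/A   20   56.0  310.0    310  199.8  0.0025  292.6  0.6417  307.1  0.9844
DP6              N/A   56  202.0  346.0    346  146.6  0.0025  256.8  0.6424  213.2  0.9872
```

The single-arm gate makes DP1–DP2 far cheaper when the drug is inactive
(expected 39 patients against 147–302), while the group-sequential DP4 is
the cheapest plan once the drug clearly works (176.7 expected patients at
the observed rates — about 25% below DP2). The `examples/` directory holds
short narrative scripts for each capability (`simon_designs.py`,
`group_sequential.py`, `compare_plans.py`, `reference_priors.py`), and the
`devplan` console script exposes the same computations from the shell
(`devplan design`, `evaluate`, `optimality`, `priors`, `reproduce`).

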