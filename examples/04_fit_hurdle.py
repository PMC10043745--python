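"""Fit the two-part hurdle model and extract plan-type marginal effects.

Follow-on testing is modelled in two parts: a logistic regression for
whether a patient tests at all, and a zero-truncated negative binomial for
how many services she uses if she does. The marginal effects translate the
count-part coefficients into services per tester relative to the
lowest-cost-sharing (coinsurance) plan type; planted effects are a few
hundredths of a service, the magnitude reported for real cohorts.
"""

import pandas as pd

import planshare as ps
from planshare.design import DesignSpec
from planshare.hurdle import effects_frame, marginal_effects
from planshare.rng import substream

rng = substream(7, "example-hurdle")
n = 60000
cohort = pd.DataFrame(
    {
        "plan_type": rng.choice(
            ["coinsurance", "balanced", "copay", "deductible"], size=n,
            p=[0.134, 0.215, 0.147, 0.504],
        ),
        "age_group": rng.choice(["40-64", "65-74"], size=n, p=[0.95, 0.05]),
        "race_ethnicity": rng.choice(
            ["Asian", "Black", "Hispanic", "White", "Unknown"], size=n,
            p=[0.036, 0.073, 0.071, 0.713, 0.107],
        ),
        "cci_category": rng.choice(["0", "1", "2", "3+"], size=n,
                                   p=[0.874, 0.104, 0.018, 0.004]),
        "region": rng.choice([f"R{i}" for i in range(1, 6)], size=n),
    }
)
params = ps.OutcomeParams.typical()
data = ps.generate_outcomes(cohort, params, seed=7)

fit = ps.fit_hurdle(data, DesignSpec(outcome="all_imaging", plan_ref="coinsurance"))
print(f"part 1 (logistic): n={fit.n_obs_part1}, loglik={fit.loglik_part1:.1f}")
print(f"part 2 (zero-truncated NB): n={fit.n_obs_part2}, "
      f"alpha={fit.alpha:.3f}, loglik={fit.loglik_part2:.1f}")

summary = fit.summary_frame()
plan_terms = summary[summary["term"].str.startswith("plan:")]
print("\nplan-type coefficients (both parts):")
print(plan_terms.round(4).to_string(index=False))

effects = marginal_effects(fit, data, apply_smearing=False)
print("\nmarginal effects, services per tester vs coinsurance plans:")
print(effects_frame(effects).round(4).to_string(index=False))
print(
    "\nNegative estimates mean testers in that plan type undergo fewer\n"
    "follow-on services than comparable testers in coinsurance plans.\n"
    "The planted effects are a few hundredths of a service, so at this\n"
    "sample size (~6500 testers) the confidence intervals rightly include\n"
    "zero; detection at these magnitudes takes cohorts in the hundreds of\n"
    "thousands, as scripts/acceptance.py demonstrates."
)
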