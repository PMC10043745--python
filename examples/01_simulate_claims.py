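"""Simulate a small claims universe and inspect cost-sharing mechanics.

Generates plans of the four mechanism-design types, one year of claims, and
prints the out-of-pocket decomposition for one enrollee in a balanced plan:
early claims fall entirely under the deductible, later claims show the
plan's copay and coinsurance once the deductible is met.
"""

import planshare as ps

plans = ps.generate_plans(
    n_plans=40, mixture=(0.25, 0.25, 0.25, 0.25), separation=2.0, seed=1
)
claims, enrollment = ps.generate_claims(plans, year=2016, seed=1)

balanced = next(p for p in plans if p.true_type == "balanced")
print(f"plan {balanced.plan_id}: type={balanced.true_type}, "
      f"copay=${balanced.copay_amount}, "
      f"coinsurance={balanced.coinsurance_rate:.1%}, "
      f"deductible=${balanced.annual_deductible}")

one = claims[claims["plan_id"] == balanced.plan_id]
eid = one["enrollee_id"].iloc[0]
cols = ["service_date", "allowed_amount", "copay", "coinsurance", "deductible"]
print(one[one["enrollee_id"] == eid][cols].to_string(index=False))
print(
    "\nEach row is one claim; the three cost-share columns always sum to at\n"
    "most the allowed amount, and the deductible column dries up once the\n"
    "enrollee's annual deductible is exhausted."
)
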