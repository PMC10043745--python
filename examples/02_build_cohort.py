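"""Build the screening-mammography cohort and episodes of care.

Simulates a study, applies the inclusion rules (female, 40+ at study start,
continuously enrolled, alive, 2016 index screen, no breast cancer in the
prior year) and constructs 365-day episodes. Prints the exclusion tally,
the subsequent-testing rate, and the out-of-pocket cost contrast between
testers and screening-only patients.
"""

import planshare as ps
from planshare.synthetic import StudyConfig, simulate_study

study = simulate_study(StudyConfig(n_plans=300, mean_enrollees_per_plan=20, seed=5))
cohort, episodes, exclusions = ps.build_cohort(study.claims, study.enrollment)

print(f"screened enrollees considered: {len(cohort) + len(exclusions)}")
print("exclusions by reason:")
print(exclusions["reason"].value_counts().to_string())
print(f"\ncohort size: {len(cohort)} "
      f"(generator planted {study.truth['n_eligible']} eligible patients)")

testers = episodes["any_subsequent"]
rate = ps.proportion(int(testers.sum()), len(episodes))
print(f"subsequent-testing rate: {rate}% "
      "(screening populations typically show ~10-12%)")
print(
    f"mean breast-imaging OOPC: "
    f"${episodes.loc[testers, 'oopc_breast_imaging'].mean():.2f} for testers vs "
    f"${episodes.loc[~testers, 'oopc_breast_imaging'].mean():.2f} for screening-only"
)
print(episodes["termination_reason"].value_counts().to_string())
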