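import pandas as pd
import pytest

from planshare.synthetic import StudyConfig, simulate_study


def make_claims(rows):
    """Claims table from (enrollee, plan, date, cpt, icd, allowed, copay, coins, ded)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "enrollee_id", "plan_id", "service_date", "cpt_code", "icd_codes",
            "allowed_amount", "copay", "coinsurance", "deductible",
        ],
    )
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


def make_enrollment(rows):
    """Enrollment table from (enrollee, plan, sex, birth_year, start, end)."""
    return pd.DataFrame(
        rows,
        columns=["enrollee_id", "plan_id", "sex", "birth_year", "enroll_start", "enroll_end"],
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across test modules."""
    return simulate_study(StudyConfig(n_plans=300, mean_enrollees_per_plan=20, seed=5))


@pytest.fixture(scope="session")
def cohort_bundle(small_study):
    from planshare.cohort import build_cohort

    cohort, episodes, exclusions = build_cohort(
        small_study.claims, small_study.enrollment
    )
    return cohort, episodes, exclusions
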