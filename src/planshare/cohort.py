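"""Study cohort and episode-of-care construction from claims.

The cohort is anchored on index screening mammograms: women aged 40+ at the
start of the study period, continuously enrolled in one plan across it, alive
at its end, with a screening mammogram in the index year and no breast-cancer
diagnosis in the preceding 12 months. Each patient's episode of care runs
from her index screen to the earlier of 365 days or her first post-index
breast-cancer diagnosis claim, and follow-on services (diagnostic
mammography, breast ultrasound, breast MRI, breast biopsy) are counted inside
the half-open window (index, end].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import charlson
from .errors import DataQualityError, InvalidConfigError

__all__ = [
    "CodeConfig",
    "identify_index_events",
    "apply_inclusion_criteria",
    "build_episodes",
    "compute_charlson",
    "compute_annual_oopc",
    "build_cohort",
]

COST_FIELDS = ["copay", "coinsurance", "deductible"]
SERVICE_CATEGORIES = ["diagnostic_mammo", "ultrasound", "mri", "biopsy"]


@dataclass(frozen=True)
class CodeConfig:
    """Procedure and diagnosis code sets that define the study's events.

    The breast-biopsy CPT list varies by site and is deliberately
    configurable; the defaults are common stereotactic/core-biopsy codes.
    """

    screening_codes: frozenset[str] = frozenset({"G0202", "77057", "77063"})
    diagnostic_mammo_codes: frozenset[str] = frozenset({"G0204", "G0206"})
    ultrasound_codes: frozenset[str] = frozenset({"76641", "76642"})
    mri_codes: frozenset[str] = frozenset({"77059"})
    biopsy_codes: frozenset[str] = frozenset({"19081", "19083", "19085"})
    cancer_dx_prefixes: frozenset[str] = frozenset({"174.", "C50."})

    def __post_init__(self) -> None:
        sets = [
            self.screening_codes, self.diagnostic_mammo_codes,
            self.ultrasound_codes, self.mri_codes, self.biopsy_codes,
        ]
        if any(len(s) == 0 for s in sets) or not self.cancer_dx_prefixes:
            raise InvalidConfigError("all code sets must be non-empty")
        seen: set[str] = set()
        for s in sets:
            if seen & s:
                raise InvalidConfigError(f"code sets overlap on {seen & s}")
            seen |= s

    def category_sets(self) -> dict[str, frozenset[str]]:
        return {
            "diagnostic_mammo": self.diagnostic_mammo_codes,
            "ultrasound": self.ultrasound_codes,
            "mri": self.mri_codes,
            "biopsy": self.biopsy_codes,
        }

    def breast_imaging_codes(self) -> frozenset[str]:
        """All breast-imaging CPTs including the index screening codes."""
        out: frozenset[str] = frozenset()
        for s in (self.screening_codes, *self.category_sets().values()):
            out |= s
        return out


def _as_dates(claims: pd.DataFrame) -> pd.DataFrame:
    if not pd.api.types.is_datetime64_any_dtype(claims["service_date"]):
        claims = claims.assign(service_date=pd.to_datetime(claims["service_date"]))
    return claims


def identify_index_events(
    claims: pd.DataFrame, codes: CodeConfig, index_year: int
) -> pd.Series:
    """Earliest qualifying screening mammogram per patient in the index year.

    Returns a Series indexed by enrollee_id; patients with no qualifying
    claim are absent.
    """
    claims = _as_dates(claims)
    m = claims["cpt_code"].astype(str).isin(codes.screening_codes) & (
        claims["service_date"].dt.year == index_year
    )
    return claims.loc[m].groupby("enrollee_id")["service_date"].min()


def _has_cancer_dx(icd: pd.Series, prefixes: frozenset[str]) -> np.ndarray:
    codes = icd.astype(str).str.split(";")
    flat = codes.explode().str.strip()
    hit = pd.Series(False, index=flat.index)
    arr = flat.to_numpy().astype(str)
    mask = np.zeros(len(arr), dtype=bool)
    for p in prefixes:
        mask |= np.char.startswith(arr, p)
    hit = pd.Series(mask, index=flat.index).groupby(level=0).any()
    return hit.reindex(icd.index, fill_value=False).to_numpy()


def apply_inclusion_criteria(
    enrollment: pd.DataFrame,
    claims: pd.DataFrame,
    index_map: pd.Series,
    codes: CodeConfig,
    study_start: str = "2015-01-01",
    study_end: str = "2017-12-31",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply cohort inclusion/exclusion rules.

    Returns ``(cohort, exclusions)`` where exclusions carries one reason code
    per rejected enrollee (first failed rule wins, evaluated in the order:
    demographics, sex, age, continuous enrollment, vital status, index event,
    prior breast cancer).
    """
    claims = _as_dates(claims)
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)
    enr = enrollment.copy()

    # continuous enrollment in *one* plan: a single enrollment span covering
    # the whole study period
    n_rows = enr.groupby("enrollee_id")["plan_id"].size()
    n_plans = enr.groupby("enrollee_id")["plan_id"].nunique()
    enr = enr.drop_duplicates("enrollee_id", keep="first").set_index("enrollee_id")

    reasons = pd.Series("", index=enr.index, dtype=object)

    missing = enr["sex"].isna() | enr["birth_year"].isna()
    reasons[missing] = "missing_demographics"

    ok = reasons == ""
    reasons[ok & (enr["sex"] != "F")] = "not_female"

    ok = reasons == ""
    age_at_start = start.year - enr["birth_year"].astype(float)
    reasons[ok & (age_at_start < 40)] = "under_40_at_study_start"

    ok = reasons == ""
    cont = (
        (pd.to_datetime(enr["enroll_start"]) <= start)
        & (pd.to_datetime(enr["enroll_end"]) >= end)
        & (n_rows.reindex(enr.index) == 1)
        & (n_plans.reindex(enr.index) == 1)
    )
    reasons[ok & ~cont] = "not_continuously_enrolled"

    ok = reasons == ""
    if "death_date" in enr.columns:
        died = pd.to_datetime(enr["death_date"]).notna() & (
            pd.to_datetime(enr["death_date"]) <= end
        )
        reasons[ok & died] = "not_alive_at_study_end"

    ok = reasons == ""
    has_index = enr.index.isin(index_map.index)
    reasons[ok & ~has_index] = "no_index_event"

    # breast-cancer diagnosis in the 365 days preceding the index date
    ok = reasons == ""
    cand = claims[claims["enrollee_id"].isin(enr.index[ok & has_index])]
    cand = cand[_has_cancer_dx(cand["icd_codes"], codes.cancer_dx_prefixes)]
    if len(cand):
        cand = cand.assign(index_date=cand["enrollee_id"].map(index_map))
        pre = cand[
            (cand["service_date"] >= cand["index_date"] - pd.Timedelta(days=365))
            & (cand["service_date"] < cand["index_date"])
        ]
        prior_ids = set(pre["enrollee_id"].unique())
        m = ok & enr.index.isin(prior_ids)
        reasons[m] = "prior_breast_cancer"

    included = reasons == ""
    cohort = enr[included].reset_index()
    cohort = cohort.rename(columns={"enrollee_id": "patient_id"})
    cohort["index_date"] = cohort["patient_id"].map(index_map)
    age_at_index = cohort["index_date"].dt.year - cohort["birth_year"].astype(int)
    bins = np.array([40, 65, 75, 85, 200])
    labels = np.array(["40-64", "65-74", "75-84", "85+"])
    cohort["age_group"] = labels[
        np.clip(np.searchsorted(bins, age_at_index, side="right") - 1, 0, 3)
    ]
    keep = ["patient_id", "plan_id", "index_date", "birth_year", "age_group"]
    for opt in ("race_ethnicity", "region"):
        if opt in cohort.columns:
            keep.append(opt)
    exclusions = (
        reasons[~included].rename("reason").rename_axis("enrollee_id").reset_index()
    )
    return cohort[keep], exclusions


def build_episodes(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    codes: CodeConfig,
    dedup_same_day: bool = False,
) -> pd.DataFrame:
    """Construct one episode of care per cohort patient.

    The episode ends at ``min(index + 365 days, first post-index breast-cancer
    claim)``; service counts are tabulated over claims with
    ``index < service_date <= end``. ``dedup_same_day`` collapses same-day
    claims with identical CPT to a single count (off by default: claim lines
    are what the tabulation counts).
    """
    claims = _as_dates(claims)
    c = claims[claims["enrollee_id"].isin(cohort["patient_id"])].copy()
    c = c.merge(
        cohort[["patient_id", "index_date"]],
        left_on="enrollee_id", right_on="patient_id", how="left",
    )

    # termination: earliest cancer-dx claim strictly after index
    ca = c[_has_cancer_dx(c["icd_codes"], codes.cancer_dx_prefixes)]
    ca = ca[ca["service_date"] > ca["index_date"]]
    ca = ca[ca["service_date"] <= ca["index_date"] + pd.Timedelta(days=365)]
    first_ca = ca.groupby("patient_id")["service_date"].min()

    ep = cohort[["patient_id", "plan_id", "index_date"]].copy()
    cap = ep["index_date"] + pd.Timedelta(days=365)
    ca_date = ep["patient_id"].map(first_ca)
    ep["end_date"] = np.where(ca_date.notna() & (ca_date < cap), ca_date, cap)
    ep["end_date"] = pd.to_datetime(ep["end_date"])
    ep["termination_reason"] = np.where(
        ca_date.notna() & (ca_date < cap), "cancer_dx", "window_365d"
    )

    c = c.merge(ep[["patient_id", "end_date"]], on="patient_id", how="left")
    in_window = (c["service_date"] > c["index_date"]) & (
        c["service_date"] <= c["end_date"]
    )
    w = c[in_window]
    if dedup_same_day:
        w = w.drop_duplicates(["patient_id", "service_date", "cpt_code"])
    for cat, cset in codes.category_sets().items():
        n = (
            w[w["cpt_code"].astype(str).isin(cset)]
            .groupby("patient_id")
            .size()
        )
        ep[f"n_{cat}"] = ep["patient_id"].map(n).fillna(0).astype(int)
    ep["n_services"] = sum(ep[f"n_{cat}"] for cat in codes.category_sets())
    ep["any_subsequent"] = ep["n_services"] > 0

    oopc = compute_annual_oopc(claims, ep["index_date"].dt.year.mode().iat[0], codes)
    ep = ep.merge(oopc, left_on="patient_id", right_on="enrollee_id", how="left")
    ep = ep.drop(columns=["enrollee_id"])
    ep[["oopc_all_medical", "oopc_breast_imaging"]] = ep[
        ["oopc_all_medical", "oopc_breast_imaging"]
    ].fillna(0.0)
    return ep


def compute_charlson(
    claims: pd.DataFrame,
    index_map: pd.Series,
    code_map: dict[str, tuple[str, int]] | None = None,
    lookback_days: int = 365,
) -> pd.DataFrame:
    """Prospective Charlson score per patient over the pre-index lookback."""
    claims = _as_dates(claims)
    c = claims[claims["enrollee_id"].isin(index_map.index)].copy()
    idx = c["enrollee_id"].map(index_map)
    m = (c["service_date"] >= idx - pd.Timedelta(days=lookback_days)) & (
        c["service_date"] < idx
    )
    c = c[m]
    scores = charlson.score_claims(c["icd_codes"], c["enrollee_id"], code_map)
    out = pd.DataFrame({"patient_id": index_map.index})
    out["cci_score"] = out["patient_id"].map(scores).fillna(0).astype(int)
    out["cci_category"] = charlson.categorize(out["cci_score"])
    return out


def compute_annual_oopc(
    claims: pd.DataFrame, year: int, codes: CodeConfig
) -> pd.DataFrame:
    """Total and breast-imaging out-of-pocket cost per enrollee for a year.

    OOPC is the sum of the copay, coinsurance and deductible components;
    the breast-imaging column restricts to claims whose CPT falls in any
    breast-imaging code set (screening included).
    """
    claims = _as_dates(claims)
    for f in COST_FIELDS:
        if (claims[f] < 0).any():
            raise DataQualityError(f"negative {f} component in claims")
    c = claims[claims["service_date"].dt.year == year].copy()
    c["oopc"] = c[COST_FIELDS].sum(axis=1)
    total = c.groupby("enrollee_id")["oopc"].sum()
    bi = (
        c[c["cpt_code"].astype(str).isin(codes.breast_imaging_codes())]
        .groupby("enrollee_id")["oopc"]
        .sum()
    )
    out = total.rename("oopc_all_medical").reset_index()
    out["oopc_breast_imaging"] = out["enrollee_id"].map(bi).fillna(0.0)
    return out


def build_cohort(
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    codes: CodeConfig | None = None,
    index_year: int = 2016,
    study_start: str = "2015-01-01",
    study_end: str = "2017-12-31",
    charlson_map: dict[str, tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """End-to-end cohort construction.

    Returns ``(cohort, episodes, exclusions)``; the cohort carries the full
    adjustment covariate set (age group, race/ethnicity, CCI category,
    region) ready for the hurdle model.
    """
    codes = codes or CodeConfig()
    index_map = identify_index_events(claims, codes, index_year)
    cohort, exclusions = apply_inclusion_criteria(
        enrollment, claims, index_map, codes, study_start, study_end
    )
    cci = compute_charlson(
        claims, index_map[index_map.index.isin(cohort["patient_id"])], charlson_map
    )
    cohort = cohort.merge(cci, on="patient_id", how="left")
    cohort["cci_score"] = cohort["cci_score"].fillna(0).astype(int)
    cohort["cci_category"] = cohort["cci_category"].fillna("0")
    episodes = build_episodes(cohort, claims, codes)
    return cohort, episodes, exclusions
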