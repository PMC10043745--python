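"""Prospective Charlson comorbidity scoring from diagnosis codes.

The score is a weighted sum over *distinct* comorbid conditions observed in a
patient's claims during a lookback window (default: the year preceding the
index event). Conditions are recognised by ICD prefix; the shipped map uses
standard Charlson weights with ICD-10 prefixes after Quan et al. plus the
classic ICD-9 rubrics, and is fully configurable — pass your own
``{prefix: (condition, weight)}`` map to reproduce any local variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = ["DEFAULT_CHARLSON_MAP", "score_claims", "categorize"]

#: condition -> (weight, icd prefixes). Dots are retained; matching is
#: prefix-based on the normalised code string.
_CONDITIONS: dict[str, tuple[int, tuple[str, ...]]] = {
    "myocardial_infarction": (1, ("I21", "I22", "I25.2", "410", "412")),
    "congestive_heart_failure": (1, ("I50", "I09.9", "I11.0", "I13.0", "I13.2", "I42", "I43", "428")),
    "peripheral_vascular": (1, ("I70", "I71", "I73.1", "I73.8", "I73.9", "I77.1", "I79.0", "K55.1", "Z95.8", "Z95.9", "440", "441", "443.9")),
    "cerebrovascular": (1, ("G45", "G46", "H34.0", "I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67", "I68", "I69", "430", "431", "432", "433", "434", "435", "436", "437", "438")),
    "dementia": (1, ("F00", "F01", "F02", "F03", "F05.1", "G30", "G31.1", "290")),
    "chronic_pulmonary": (1, ("J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47", "J60", "J61", "J62", "J63", "J64", "J65", "J66", "J67", "490", "491", "492", "493", "494", "495", "496")),
    "rheumatic": (1, ("M05", "M06", "M31.5", "M32", "M33", "M34", "M35.1", "M35.3", "M36.0", "710.0", "710.1", "710.4", "714")),
    "peptic_ulcer": (1, ("K25", "K26", "K27", "K28", "531", "532", "533", "534")),
    "mild_liver": (1, ("B18", "K70.0", "K70.1", "K70.2", "K70.3", "K70.9", "K71.3", "K71.4", "K71.5", "K71.7", "K73", "K74", "K76.0", "Z94.4", "571.2", "571.5", "571.6")),
    "diabetes": (1, ("E10.0", "E10.1", "E10.6", "E10.8", "E10.9", "E11.0", "E11.1", "E11.6", "E11.8", "E11.9", "E13.9", "250.0", "250.1", "250.2", "250.3")),
    "diabetes_complicated": (2, ("E10.2", "E10.3", "E10.4", "E10.5", "E11.2", "E11.3", "E11.4", "E11.5", "250.4", "250.5", "250.6")),
    "hemiplegia": (2, ("G04.1", "G11.4", "G80.1", "G80.2", "G81", "G82", "342", "343", "344")),
    "renal": (2, ("N18", "N19", "N03.2", "N05.2", "Z49", "Z94.0", "582", "583", "585", "586", "588.0")),
    "malignancy": (2, ("C0", "C1", "C2", "C3", "C4", "C5", "C6", "C70", "C71", "C72", "C73", "C74", "C75", "C76", "C81", "C82", "C83", "C84", "C85", "C88", "C90", "C91", "C92", "C93", "C94", "C95", "C96", "C97", "14", "15", "16", "17", "18", "19", "200", "201", "202", "203", "204", "205", "206", "207", "208")),
    "severe_liver": (3, ("I85.0", "I85.9", "I86.4", "I98.2", "K70.4", "K71.1", "K72.1", "K72.9", "K76.5", "K76.6", "K76.7", "572.2", "572.3", "572.4")),
    "metastatic": (6, ("C77", "C78", "C79", "C80", "196", "197", "198", "199")),
    "aids": (6, ("B20", "B21", "B22", "B24", "042", "043", "044")),
}

DEFAULT_CHARLSON_MAP: dict[str, tuple[str, int]] = {
    prefix: (cond, weight)
    for cond, (weight, prefixes) in _CONDITIONS.items()
    for prefix in prefixes
}


def score_claims(
    icd_codes: pd.Series,
    patient_ids: pd.Series,
    code_map: dict[str, tuple[str, int]] | None = None,
) -> pd.Series:
    """Charlson score per patient from already-windowed diagnosis codes.

    ``icd_codes`` holds semicolon-joined code strings aligned with
    ``patient_ids``. Each condition counts once per patient regardless of how
    many claims carry it.
    """
    code_map = DEFAULT_CHARLSON_MAP if code_map is None else code_map
    if not code_map:
        raise InvalidConfigError("Charlson code map must be non-empty")

    df = pd.DataFrame({"pid": patient_ids.to_numpy(), "icd": icd_codes.to_numpy()})
    df = df[df["icd"].astype(str).str.len() > 0]
    if df.empty:
        return pd.Series(dtype=int)
    df = df.assign(icd=df["icd"].astype(str).str.split(";")).explode("icd")
    df["icd"] = df["icd"].str.strip()
    df = df[df["icd"] != ""]

    # longest prefix wins so e.g. E11.2 (complicated) shadows E11 rubrics
    hits = []
    codes = df["icd"].to_numpy()
    matched_len = np.zeros(len(df), dtype=int)
    cond_idx = np.full(len(df), -1, dtype=int)
    cond_names = []
    for j, (prefix, (cond, weight)) in enumerate(code_map.items()):
        cond_names.append((cond, weight))
        m = np.char.startswith(codes.astype(str), prefix) & (len(prefix) > matched_len)
        matched_len[m] = len(prefix)
        cond_idx[m] = j
    ok = cond_idx >= 0
    if not ok.any():
        return pd.Series(dtype=int)
    out = pd.DataFrame(
        {
            "pid": df["pid"].to_numpy()[ok],
            "condition": [cond_names[i][0] for i in cond_idx[ok]],
            "weight": [cond_names[i][1] for i in cond_idx[ok]],
        }
    )
    distinct = out.drop_duplicates(["pid", "condition"])
    return distinct.groupby("pid")["weight"].sum()


def categorize(score: pd.Series | np.ndarray) -> np.ndarray:
    """Bin integer scores into the reporting categories 0 / 1 / 2 / 3+."""
    s = np.asarray(score, dtype=int)
    return np.where(s >= 3, "3+", s.astype(str))
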