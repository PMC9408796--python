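"""GHQ-12 scoring: Likert sums, 0-0-1-1 interpreted scores, caseness, summaries.

Two standard scoring systems for the 12-item questionnaire with categories
0..3 ("better/healthier than usual" .. "much worse/more than usual"):

* Likert sum — raw categories summed, range 0 (no distress) to 36 (maximum).
* interpreted (0-0-1-1) score — categories 0/1 recoded to 0 and 2/3 to 1,
  then summed, range 0 to 12; a score of 3 or more classifies the
  person-wave as a psychological-distress case.

Scoring is complete-case: a person-wave missing any of the 12 items yields
missing scores (no proration is applied).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "likert_sum",
    "interpreted_score",
    "caseness",
    "score_waves",
    "descriptive_summary",
    "round_half_up",
]

N_ITEMS = 12
CASE_THRESHOLD = 3


def _validate_vector(responses):
    arr = np.asarray(responses, dtype=float)
    if arr.ndim != 1 or arr.size != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item responses, got shape {arr.shape}")
    observed = ~np.isnan(arr)
    vals = arr[observed]
    if np.any((vals < 0) | (vals > 3) | (vals != np.round(vals))):
        raise ValueError("item categories must be integers in {0,1,2,3}")
    return arr, observed.all()


def likert_sum(responses):
    """Sum of the 12 raw categories (0-36); NaN if any item is missing."""
    arr, complete = _validate_vector(responses)
    if not complete:
        return float("nan")
    return float(arr.sum())


def interpreted_score(responses):
    """0-0-1-1 score: count of items with category >= 2 (0-12); NaN if incomplete."""
    arr, complete = _validate_vector(responses)
    if not complete:
        return float("nan")
    return float((arr >= 2).sum())


def caseness(score):
    """Psychological-distress classification: interpreted score of 3 or more."""
    if isinstance(score, float) and math.isnan(score):
        return float("nan")
    if not 0 <= score <= 12:
        raise ValueError(f"interpreted score out of range 0-12: {score}")
    return bool(score >= CASE_THRESHOLD)


def round_half_up(x):
    """Round to nearest integer with halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def score_waves(responses: pd.DataFrame, n_items: int = N_ITEMS) -> pd.DataFrame:
    """Score every person-wave of a long-format response table.

    Returns one row per (person_id, wave) with ``likert_sum``,
    ``interpreted_score`` and ``case`` (all missing unless the person-wave
    has all ``n_items`` items observed).
    """
    obs = responses.dropna(subset=["response"])
    vals = obs["response"].to_numpy(float)
    if np.any((vals < 0) | (vals > 3) | (vals != np.round(vals))):
        raise ValueError("item categories must be integers in {0,1,2,3}")
    grouped = obs.groupby(["person_id", "wave"])["response"]
    agg = grouped.agg(
        n_obs="count", raw_sum="sum", interp=lambda s: float((s >= 2).sum())
    )
    complete = agg["n_obs"] == n_items
    out = agg.reset_index()[["person_id", "wave"]]
    out["likert_sum"] = np.where(complete, agg["raw_sum"], np.nan)
    out["interpreted_score"] = np.where(complete, agg["interp"], np.nan)
    out["case"] = np.where(
        complete, agg["interp"] >= CASE_THRESHOLD, np.nan
    )
    return out


def descriptive_summary(
    scored: pd.DataFrame,
    persons: pd.DataFrame,
    responses: pd.DataFrame | None = None,
    n_items: int = N_ITEMS,
) -> dict:
    """Cohort and per-wave descriptive tables.

    Returns ``{"cohort": ..., "waves": ...}``.  The cohort table carries sex
    and diarrhoea counts with display percentages (rounded half-up) and raw
    proportions; the wave table carries respondent counts, case counts and
    percentages, Likert-sum and interpreted-score means/SDs, and, when the
    raw response table is given, per-wave item-response coverage.
    """
    n = len(persons)
    cohort_rows = [{"characteristic": "n_persons", "count": n, "percent": None,
                    "proportion": None}]
    for label, mask in [
        ("men", persons["sex"] == 1),
        ("women", persons["sex"] == 0),
        ("diarrhoea_trip", persons.get("diarrhoea_trip", pd.Series(dtype=int)) == 1),
        ("diarrhoea_after", persons.get("diarrhoea_after", pd.Series(dtype=int)) == 1),
    ]:
        count = int(mask.sum())
        prop = count / n if n else float("nan")
        cohort_rows.append(
            {
                "characteristic": label,
                "count": count,
                "percent": round_half_up(100 * prop) if n else None,
                "proportion": prop,
            }
        )
    cohort = pd.DataFrame(cohort_rows)

    waves = sorted(scored["wave"].unique())
    wave_rows = []
    for w in waves:
        sw = scored[scored["wave"] == w]
        complete = sw.dropna(subset=["interpreted_score"])
        n_resp = len(complete)
        n_cases = int((complete["case"] == 1).sum()) if n_resp else 0
        row = {
            "wave": w,
            "n_respondents": n_resp,
            "n_cases": n_cases,
            "case_percent": round_half_up(100 * n_cases / n_resp) if n_resp else None,
            "case_proportion": n_cases / n_resp if n_resp else float("nan"),
            "likert_mean": complete["likert_sum"].mean() if n_resp else float("nan"),
            "likert_sd": complete["likert_sum"].std(ddof=1) if n_resp > 1 else float("nan"),
            "interp_mean": complete["interpreted_score"].mean() if n_resp else float("nan"),
            "interp_sd": complete["interpreted_score"].std(ddof=1)
            if n_resp > 1
            else float("nan"),
        }
        if responses is not None:
            total = n * n_items
            n_obs = int(
                responses[(responses["wave"] == w)]["response"].notna().sum()
            )
            row["n_item_responses"] = n_obs
            row["coverage_proportion"] = n_obs / total if total else float("nan")
            row["coverage_percent"] = round_half_up(100 * n_obs / total) if total else None
        wave_rows.append(row)
    return {"cohort": cohort, "waves": pd.DataFrame(wave_rows)}
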