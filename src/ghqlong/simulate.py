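"""Synthetic cohorts emulating a three-wave travel questionnaire study.

The generator reproduces the statistical structure the downstream analysis
assumes: a cohort of adult travellers (N=174, 27% men, ages 18-65) assessed
with a 12-item ordinal questionnaire at three occasions (before the trip, at
return, one month later), a latent distress trait with wave and covariate
effects on the graded-response scale, season-of-year structure through 16
distinct trip-return dates, travellers'-diarrhoea covariates (71% during the
trip, 13% after), and wave-structured attrition that deletes whole
person-waves (item-level gaps are rare, at most a couple of partial
responders), targeting per-wave item-response coverage of roughly
98% / 76% / 72%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import grm

__all__ = [
    "CohortConfig",
    "ItemParameterSet",
    "default_trip_dates",
    "generate_cohort",
    "draw_item_parameters",
    "simulate_item_responses",
    "apply_attrition",
    "simulate_study",
]

#: latent-scale covariate effects used as the default generating truth;
#: waves lower distress (strongly at return, partly lasting), diarrhoea
#: after return raises it, diarrhoea during the trip slightly lowers it.
DEFAULT_EFFECTS = {
    "sex2": -0.06,
    "age_z": -0.05,
    "wave1": -0.63,
    "wave2": -0.21,
    "cos_t": 0.01,
    "sin_t": -0.18,
    "diarrhoea_trip": -0.24,
    "diarrhoea_after": 0.53,
}

#: default item-structure scales (log-discrimination SD, threshold-shift SD,
#: their correlation, and shared base thresholds on the latent logit scale)
DEFAULT_RE_SD_DISC = 0.32
DEFAULT_RE_SD_THR = 1.29
DEFAULT_RE_COR = 0.35
DEFAULT_SHARED_THRESHOLDS = (-1.5, 2.7, 6.2)


def default_trip_dates(n_dates: int = 16):
    """16 equally spaced trip-return dates from 2018-08-12 to 2019-03-10."""
    start = pd.Timestamp("2018-08-12")
    end = pd.Timestamp("2019-03-10")
    return list(pd.date_range(start, end, periods=n_dates))


@dataclass
class CohortConfig:
    """Generating conditions for a synthetic cohort."""

    n_persons: int = 174
    frac_men: float = 0.27
    age_range: tuple = (18, 65)
    n_items: int = 12
    n_waves: int = 3
    trip_return_dates: list = field(default_factory=default_trip_dates)
    trip_date_weights: list | None = None
    diarrhoea_trip_rate: float = 0.71
    diarrhoea_after_rate: float = 0.13
    true_effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    person_sd: float = 1.0
    coverage_targets: tuple = (0.98, 0.76, 0.72)
    max_partial_responders: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_men", "diarrhoea_trip_rate", "diarrhoea_after_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_items < 2:
            raise ValueError("n_items must be at least 2")
        if self.n_waves < 2:
            raise ValueError("n_waves must be at least 2")
        if len(self.coverage_targets) != self.n_waves:
            raise ValueError("coverage_targets must have one entry per wave")
        if not all(0.0 <= c <= 1.0 for c in self.coverage_targets):
            raise ValueError("coverage targets must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must satisfy min < max")
        if not self.trip_return_dates:
            raise ValueError("trip_return_dates must be non-empty")


@dataclass
class ItemParameterSet:
    """Per-item graded-response parameters and the scales that generated them."""

    item_id: np.ndarray
    log_disc: np.ndarray
    thresholds: np.ndarray  # (n_items, 3), strictly increasing rows
    shared_thresholds: np.ndarray
    item_threshold_shift: np.ndarray
    re_sd_disc: float
    re_sd_thr: float
    re_cor: float

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.log_disc = np.asarray(self.log_disc, dtype=float)
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("item thresholds must be strictly increasing")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw the person-level table: sex, age, trip-return date, diarrhoea flags.

    Sex is Bernoulli(frac_men) (1 = man, 0 = woman), age uniform on the
    configured range and standardized into ``age_z``, trip-return dates drawn
    from the configured list (uniformly unless weights are given), and the
    two diarrhoea flags drawn independently at their configured rates.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    sex = (rng.random(n) < config.frac_men).astype(int)
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    dates = pd.to_datetime(pd.Series(config.trip_return_dates))
    weights = config.trip_date_weights
    if weights is None:
        probs = np.full(len(dates), 1.0 / len(dates))
    else:
        probs = np.asarray(weights, dtype=float)
        probs = probs / probs.sum()
    date_idx = rng.choice(len(dates), size=n, p=probs)
    trip_dates = dates.iloc[date_idx].reset_index(drop=True)
    t_days = (trip_dates - grm.TRIP_ORIGIN).dt.days.astype(int)
    if (t_days < 0).any():
        raise ValueError("trip return dates precede the study origin date")
    persons = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "sex": sex,
            "age": age,
            "age_z": (age - age.mean()) / age.std(ddof=1),
            "trip_return_date": trip_dates.dt.date.astype(str),
            "t_days": t_days,
            "diarrhoea_trip": (rng.random(n) < config.diarrhoea_trip_rate).astype(int),
            "diarrhoea_after": (rng.random(n) < config.diarrhoea_after_rate).astype(int),
        }
    )
    return persons


def draw_item_parameters(
    n_items: int = 12,
    re_sd_disc: float = DEFAULT_RE_SD_DISC,
    re_sd_thr: float = DEFAULT_RE_SD_THR,
    re_cor: float = DEFAULT_RE_COR,
    shared_thresholds=DEFAULT_SHARED_THRESHOLDS,
    disc_intercept: float = 0.06,
    threshold_gap_jitter_sd: float = 0.0,
    seed: int = 0,
) -> ItemParameterSet:
    """Draw per-item parameters around shared thresholds.

    (log-discrimination deviation, threshold shift) pairs come from a
    bivariate normal with SDs ``re_sd_disc``/``re_sd_thr`` and correlation
    ``re_cor``; each item's thresholds are the shared thresholds plus its
    scalar shift.  ``threshold_gap_jitter_sd > 0`` additionally perturbs each
    item's threshold *gaps* on the log scale, producing genuinely
    item-specific threshold patterns (beyond a common shift) while preserving
    ordering.
    """
    shared = np.asarray(shared_thresholds, dtype=float)
    if np.any(np.diff(shared) <= 0):
        raise ValueError("shared thresholds must be strictly increasing")
    if not -1.0 <= re_cor <= 1.0:
        raise ValueError("|re_cor| must be at most 1")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [re_sd_disc**2, re_cor * re_sd_disc * re_sd_thr],
            [re_cor * re_sd_disc * re_sd_thr, re_sd_thr**2],
        ]
    )
    # safe Cholesky-free draw that tolerates zero variances
    z = rng.standard_normal((n_items, 2))
    w = np.sqrt(max(1.0 - re_cor**2, 0.0))
    disc_dev = re_sd_disc * z[:, 0]
    shift = re_sd_thr * (re_cor * z[:, 0] + w * z[:, 1])
    del cov

    thresholds = shared[None, :] + shift[:, None]
    if threshold_gap_jitter_sd > 0:
        gaps = np.diff(shared)
        jitter = rng.normal(0.0, threshold_gap_jitter_sd, size=(n_items, len(gaps)))
        new_gaps = gaps[None, :] * np.exp(jitter)
        first = thresholds[:, 0] + rng.normal(
            0.0, threshold_gap_jitter_sd, size=n_items
        )
        thresholds = np.concatenate(
            [first[:, None], first[:, None] + np.cumsum(new_gaps, axis=1)], axis=1
        )
    return ItemParameterSet(
        item_id=np.arange(1, n_items + 1),
        log_disc=disc_intercept + disc_dev,
        thresholds=thresholds,
        shared_thresholds=shared,
        item_threshold_shift=shift,
        re_sd_disc=re_sd_disc,
        re_sd_thr=re_sd_thr,
        re_cor=re_cor,
    )


def simulate_item_responses(
    persons: pd.DataFrame,
    items: ItemParameterSet,
    effects: dict | None = None,
    person_sd: float = 1.0,
    n_waves: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a complete long-format ordinal response table.

    Each person receives one latent intercept ``theta_p ~ Normal(0,
    person_sd)``; the linear predictor adds the configured latent-scale
    covariate effects via the model design matrix, and each
    person-wave-item category is drawn from the cumulative-logit graded
    response probabilities.  Deterministic given ``seed``.
    """
    effects = dict(DEFAULT_EFFECTS) if effects is None else dict(effects)
    design = grm.build_design(persons, n_waves=n_waves, spec="m5")
    unknown = [k for k in effects if k not in design.columns]
    if unknown:
        raise ValueError(f"unknown covariates in effects map: {unknown}")
    rng = np.random.default_rng(seed)
    n = len(persons)
    theta = rng.normal(0.0, person_sd, size=n)
    beta = np.array([effects.get(c, 0.0) for c in design.columns])
    eta_rows = design.to_numpy(float) @ beta

    person_ids = persons["person_id"].to_numpy()
    n_items = len(items.item_id)
    records = []
    # design rows are ordered wave-major, matching build_design construction
    for w in range(n_waves):
        eta_w = theta + eta_rows[w * n : (w + 1) * n]
        probs = grm.category_probabilities(
            eta_w[:, None] * np.ones((1, n_items)),
            items.log_disc[None, :] * np.ones((n, 1)),
            items.thresholds[None, :, :] * np.ones((n, 1, 1)),
        )
        cum = np.cumsum(probs, axis=-1)
        u = rng.random((n, n_items))
        cats = (u[..., None] > cum[..., :-1]).sum(axis=-1)
        records.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(person_ids, n_items),
                    "wave": w,
                    "item": np.tile(items.item_id, n),
                    "response": cats.reshape(-1),
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    out["response"] = out["response"].astype(float)
    return out


def apply_attrition(
    responses: pd.DataFrame,
    coverage_targets,
    max_partial_responders: int = 2,
    seed: int = 0,
    distress_weight: float = 0.0,
) -> pd.DataFrame:
    """Delete records to hit per-wave coverage targets, person-wave first.

    Missingness is imposed by deleting whole person-waves until each wave's
    item-response coverage is as close as achievable to its target; when the
    exact target requires a fraction of a person-wave and the partial-
    responder budget allows, one extra person per wave loses only some items.
    Observed values are never altered.  ``distress_weight > 0`` makes
    deletion probability increase with the person's raw wave sum (a
    missing-not-at-random stress mode); the default is missing completely at
    random.
    """
    targets = list(coverage_targets)
    if not all(0.0 <= t <= 1.0 for t in targets):
        raise ValueError("coverage targets must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = responses.copy()
    persons = np.sort(responses["person_id"].unique())
    items_per_wave = {
        w: responses.loc[responses["wave"] == w, "item"].nunique()
        for w in range(len(targets))
    }
    partial_budget = int(max_partial_responders)
    drop_index = []
    for w, target in enumerate(targets):
        wave_rows = out[out["wave"] == w]
        n_items = items_per_wave[w]
        total = len(wave_rows)
        if total == 0:
            continue
        n_missing = int(round((1.0 - target) * total))
        if n_missing == 0:
            continue
        whole = n_missing // n_items
        rem = n_missing % n_items
        use_partial = rem > 0 and partial_budget > 0
        if not use_partial:
            whole = int(round(n_missing / n_items))
            rem = 0
        n_delete = whole + (1 if use_partial else 0)
        n_delete = min(n_delete, len(persons))

        if distress_weight > 0:
            sums = wave_rows.groupby("person_id")["response"].sum()
            s = sums.reindex(persons).fillna(sums.mean())
            z = (s - s.mean()) / (s.std(ddof=0) + 1e-9)
            wts = np.exp(distress_weight * z.to_numpy())
            wts = wts / wts.sum()
        else:
            wts = None
        chosen = rng.choice(persons, size=n_delete, replace=False, p=wts)
        whole_persons, partial_person = (
            (chosen[:-1], chosen[-1]) if use_partial else (chosen, None)
        )
        mask = (out["wave"] == w) & out["person_id"].isin(whole_persons)
        drop_index.extend(out.index[mask])
        if partial_person is not None:
            rows = out.index[(out["wave"] == w) & (out["person_id"] == partial_person)]
            drop_index.extend(rng.choice(rows, size=rem, replace=False))
            partial_budget -= 1
    return out.drop(index=drop_index).reset_index(drop=True)


def simulate_study(config: CohortConfig, items: ItemParameterSet | None = None):
    """Full generator pipeline: cohort, item parameters, responses, attrition.

    Returns ``(persons, items, complete_responses, observed_responses)``.
    Sub-stage seeds are derived deterministically from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    persons = generate_cohort(replace(config, seed=int(ss[0])))
    if items is None:
        items = draw_item_parameters(n_items=config.n_items, seed=int(ss[1]))
    complete = simulate_item_responses(
        persons,
        items,
        effects=config.true_effects,
        person_sd=config.person_sd,
        n_waves=config.n_waves,
        seed=int(ss[2]),
    )
    observed = apply_attrition(
        complete,
        config.coverage_targets,
        max_partial_responders=config.max_partial_responders,
        seed=int(ss[3]),
    )
    return persons, items, complete, observed
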