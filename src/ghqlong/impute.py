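"""Multiple imputation by chained equations with predictive mean matching.

Item responses are imputed at the item level in wide format (one column per
wave-item combination) with fully observed person covariates as predictors,
using chained equations and predictive mean matching (PMM): each missing
cell receives the observed value of a donor whose model-predicted mean is
closest, so imputations are always members of the observed category set
{0..3}.  Fitting across the ``m`` completed datasets pools posterior draws
with equal weight — the standard Bayesian combining rule for multiply
imputed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.imputation.mice import MICEData

from .grm import GradedResponseModel, PosteriorDraws

__all__ = [
    "ImputationConfig",
    "ChainedPMMImputer",
    "responses_to_wide",
    "wide_to_responses",
    "pmm_chained_impute",
    "fit_pooled",
]

_COVARIATE_COLS = ["sex", "age_z", "diarrhoea_trip", "diarrhoea_after", "t_days"]


@dataclass
class ImputationConfig:
    """Number of completed datasets, PMM donor-pool size, sweeps, seed."""

    m: int = 100
    pmm_donors: int = 5
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be at least 1")


def _item_col(wave, item):
    return f"y{wave}_{item}"


def responses_to_wide(responses: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Pivot long responses to one row per person, one column per wave-item."""
    wide = responses.pivot_table(
        index="person_id", columns=["wave", "item"], values="response", dropna=False
    )
    wide.columns = [_item_col(w, i) for w, i in wide.columns]
    cov = persons.set_index("person_id")[
        [c for c in _COVARIATE_COLS if c in persons.columns]
    ]
    return cov.join(wide, how="left")


def wide_to_responses(wide: pd.DataFrame) -> pd.DataFrame:
    """Back-transform a wide completed dataset to the long response format."""
    item_cols = [c for c in wide.columns if c.startswith("y")]
    records = []
    for c in item_cols:
        w, i = c[1:].split("_")
        records.append(
            pd.DataFrame(
                {
                    "person_id": wide.index,
                    "wave": int(w),
                    "item": int(i),
                    "response": wide[c].to_numpy(float),
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["wave", "person_id", "item"]).reset_index(drop=True)


class ChainedPMMImputer(BaseEstimator):
    """MICE-PMM imputer for wide-format ordinal item columns.

    Parameters mirror :class:`ImputationConfig`.  ``fit_transform`` returns a
    list of ``m`` completed copies of the input; observed cells are never
    altered and imputed cells always take observed donor values.
    """

    def __init__(self, m=100, pmm_donors=5, max_iterations=10, seed=0):
        self.m = m
        self.pmm_donors = pmm_donors
        self.max_iterations = max_iterations
        self.seed = seed

    def fit_transform(self, wide: pd.DataFrame) -> list[pd.DataFrame]:
        cfg = ImputationConfig(
            m=self.m,
            pmm_donors=self.pmm_donors,
            max_iterations=self.max_iterations,
            seed=self.seed,
        )
        item_cols = [c for c in wide.columns if c.startswith("y")]
        other_cols = [c for c in wide.columns if not c.startswith("y")]
        if wide[other_cols].isna().any().any():
            raise ValueError("missingness outside item-response columns")
        fully_observed = [c for c in wide.columns if wide[c].notna().all()]
        if not fully_observed:
            raise ValueError("need at least one fully observed variable")
        empty = [c for c in item_cols if wide[c].notna().sum() == 0]
        if empty:
            raise ValueError(f"columns with zero observed values: {empty}")

        if not wide[item_cols].isna().any().any():
            return [wide.copy() for _ in range(cfg.m)]

        observed_mask = wide.notna()
        np.random.seed(cfg.seed % (2**31))
        mice_data = MICEData(wide.reset_index(drop=True), k_pmm=cfg.pmm_donors)
        # each item's imputation model: person covariates plus the same item
        # at the other waves (missingness is person-wave structured, so the
        # other waves carry the person-level signal; a full 40-column model
        # would be ill-conditioned at this sample size)
        for col in item_cols:
            _, item = col[1:].split("_")
            same_item = [
                c for c in item_cols if c != col and c.endswith(f"_{item}")
            ]
            predictors = other_cols + same_item
            mice_data.set_imputer(col, formula=" + ".join(predictors))
        completed = []
        for _ in range(cfg.m):
            mice_data.update_all(cfg.max_iterations)
            df = mice_data.data.copy()
            df.index = wide.index
            # chained-equation output must preserve observed cells exactly
            mask = observed_mask.to_numpy()
            if not np.allclose(
                df.to_numpy(float)[mask], wide.to_numpy(float)[mask]
            ):
                raise RuntimeError("imputation altered an observed cell")
            completed.append(df)
        return completed

    # alias so the imputer also composes where fit/transform are called separately
    def fit(self, wide: pd.DataFrame):
        self.completed_ = self.fit_transform(wide)
        return self

    def transform(self, wide=None):
        return self.completed_


def pmm_chained_impute(
    responses: pd.DataFrame,
    persons: pd.DataFrame,
    config: ImputationConfig | None = None,
    **kwargs,
) -> list[pd.DataFrame]:
    """Impute missing item responses; returns ``m`` completed long tables.

    The long-format ``responses`` may omit unobserved person-wave-item rows
    entirely or carry them with missing values; the output tables are fully
    complete over the persons-by-waves-by-items grid.
    """
    config = config or ImputationConfig(**kwargs)
    wide = responses_to_wide(responses, persons)
    imputer = ChainedPMMImputer(
        m=config.m,
        pmm_donors=config.pmm_donors,
        max_iterations=config.max_iterations,
        seed=config.seed,
    )
    completed = imputer.fit_transform(wide)
    return [wide_to_responses(df) for df in completed]


def fit_pooled(
    datasets: list[pd.DataFrame],
    persons: pd.DataFrame,
    variant: str = "m1",
    seed: int = 0,
    **sampler_kwargs,
) -> PosteriorDraws:
    """Fit the GRM to each completed dataset and pool posterior draws.

    The pooled posterior is the equal-weight concatenation of the
    per-dataset draws (stacked along the chain axis); convergence is
    assessed per dataset, and the pooled result is flagged non-converged if
    any per-dataset fit fails its R-hat gate.
    """
    if not datasets:
        raise ValueError("no completed datasets given")
    cols = None
    fits = []
    seeds = np.random.SeedSequence(seed).generate_state(len(datasets)) % (2**31)
    for k, data in enumerate(datasets):
        if cols is None:
            cols = list(data.columns)
        elif list(data.columns) != cols:
            raise ValueError("completed datasets do not share a schema")
        model = GradedResponseModel(variant=variant, seed=int(seeds[k]), **sampler_kwargs)
        model.fit(data, persons)
        fits.append(model.draws_)

    pooled_params = {
        name: np.concatenate([f.params[name] for f in fits], axis=0)
        for name in fits[0].params
    }
    pooled = PosteriorDraws(params=pooled_params)
    pooled.meta = dict(fits[0].meta)
    pooled.meta.update(
        {
            "pooled": True,
            "m": len(datasets),
            "per_dataset_converged": [bool(f.converged) for f in fits],
        }
    )
    pooled.converged = all(bool(f.converged) for f in fits)
    return pooled
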