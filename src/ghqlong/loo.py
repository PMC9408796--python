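"""Pointwise predictive density and PSIS leave-one-out model comparison.

The observation unit is one item response (person-wave-item), matching the
pointwise factorization of the graded-response likelihood.  LOOIC is
-2 * elpd_loo; the difference between two models' LOOICs is reported with a
standard error computed from the paired pointwise elpd differences.  Sign
convention: ``delta = looic(a) - looic(b)``, so a negative delta means the
first-listed model attains the lower (better) LOOIC; output headers state
this explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .grm import PosteriorDraws, category_probabilities

__all__ = ["LOOResult", "pointwise_loglik", "psis_loo", "compare_models"]

PARETO_K_WARN = 0.7


@dataclass
class LOOResult:
    """PSIS-LOO estimate: elpd, its SE, pointwise values and Pareto-k diagnostics."""

    elpd_loo: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_observations: int
    n_draws: int
    meta: dict = field(default_factory=dict)

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def frac_k_high(self) -> float:
        return float(np.mean(self.pareto_k > PARETO_K_WARN))

    def as_row(self, label=""):
        return {
            "model": label,
            "elpd_loo": self.elpd_loo,
            "looic": self.looic,
            "se": self.se,
            "pct_pareto_k_high": 100 * self.frac_k_high,
        }


def pointwise_loglik(
    draws: PosteriorDraws, responses: pd.DataFrame, design: pd.DataFrame
) -> np.ndarray:
    """Per-draw, per-observation log likelihood array of shape (S, N).

    Observations are the non-missing rows of ``responses`` in row order;
    draws are flattened across chains.
    """
    obs = responses.dropna(subset=["response"])
    y = obs["response"].to_numpy(float)
    if np.any((y < 0) | (y > 3) | (y != np.round(y))):
        raise ValueError("responses must be integer categories in {0,1,2,3}")
    y = y.astype(int)
    meta = draws.meta
    columns = meta["columns"]
    person_index = np.asarray(meta["person_index"])
    item_ids = np.asarray(meta["item_ids"])
    person_pos = {pid: k for k, pid in enumerate(person_index)}
    item_pos = {int(i): k for k, i in enumerate(item_ids)}

    beta = np.stack(
        [draws.stacked(f"b_{c}") for c in columns], axis=-1
    )  # (S, J)
    theta = draws.stacked("theta")  # (S, P)
    log_disc = draws.stacked("log_disc")  # (S, I)
    thresholds = draws.stacked("thresholds")  # (S, I, 3)
    if theta.shape[1] != len(person_index):
        raise ValueError("draws and data disagree on the number of persons")

    row_pos = design.index.get_indexer(
        pd.MultiIndex.from_arrays([obs["person_id"], obs["wave"]])
    )
    if np.any(row_pos < 0):
        raise ValueError("observation without matching design row")
    ppos = obs["person_id"].map(person_pos).to_numpy(int)
    ipos = obs["item"].astype(int).map(item_pos).to_numpy(int)
    X = design.to_numpy(float)

    S = beta.shape[0]
    N = len(y)
    out = np.empty((S, N))
    eta_rows = beta @ X.T  # (S, R)
    chunk = max(1, int(2e7) // max(N, 1))
    for s0 in range(0, S, chunk):
        s1 = min(s0 + chunk, S)
        eta = theta[s0:s1][:, ppos] + eta_rows[s0:s1][:, row_pos]
        probs = category_probabilities(
            eta, log_disc[s0:s1][:, ipos], thresholds[s0:s1][:, ipos, :]
        )
        picked = np.take_along_axis(probs, y[None, :, None], axis=-1)[..., 0]
        out[s0:s1] = np.log(np.clip(picked, 1e-300, None))
    return out


def psis_loo(loglik: np.ndarray, reff: float = 1.0) -> LOOResult:
    """Pareto-smoothed importance-sampling LOO from a (draws, obs) array."""
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("log-likelihood array must be (draws, observations)")
    S, N = loglik.shape
    if S < 2:
        raise ValueError("need at least two posterior draws")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("log-likelihood array contains non-finite values")
    if np.allclose(loglik.std(axis=0), 0.0):
        raise ValueError("degenerate input: identical draws (zero-variance weights)")
    idata = az.from_dict(
        posterior={"dummy": np.zeros((1, S))},
        log_likelihood={"y": loglik[None, :, :]},
    )
    res = az.loo(idata, pointwise=True, reff=reff)
    pointwise = np.asarray(res.loo_i.values, dtype=float)
    pareto_k = np.asarray(res.pareto_k.values, dtype=float)
    return LOOResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        pointwise=pointwise,
        pareto_k=pareto_k,
        n_observations=N,
        n_draws=S,
    )


def compare_models(a: LOOResult, b: LOOResult):
    """LOOIC difference ``looic(a) - looic(b)`` with paired-difference SE.

    Negative values favour model ``a`` (it has the smaller LOOIC).  Errors
    if the two results were not computed on the same observation set size.
    """
    if a.n_observations != b.n_observations:
        raise ValueError("LOO results computed on different observation counts")
    d = a.pointwise - b.pointwise
    se_elpd = float(np.sqrt(len(d) * np.var(d, ddof=0)))
    delta_looic = a.looic - b.looic
    return {
        "delta_looic": float(delta_looic),
        "se_delta_looic": 2.0 * se_elpd,
        "delta_elpd": float(d.sum()),
        "se_delta_elpd": se_elpd,
        "note": "delta_looic = looic(a) - looic(b); negative favours model a",
    }


def comparison_table(results: dict[str, LOOResult], reference: str) -> pd.DataFrame:
    """Comparison report across named models against a reference model."""
    rows = []
    for name, res in results.items():
        row = res.as_row(name)
        if name != reference:
            cmp = compare_models(res, results[reference])
            row["delta_looic_vs_ref"] = cmp["delta_looic"]
            row["se_delta_looic"] = cmp["se_delta_looic"]
        else:
            row["delta_looic_vs_ref"] = 0.0
            row["se_delta_looic"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)
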