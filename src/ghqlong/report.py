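"""Posterior-predictive checks in GHQ-12 sum units and seasonal effect curves.

``predict_wave_sums`` simulates item responses from posterior draws for the
observed complete person-waves and compares predicted per-wave mean/SD of
the 0-36 Likert sum with the observed values — the model check in the units
readers of the questionnaire know.  ``seasonal_effect_curve`` summarizes,
for each unique trip-return date, the posterior of the total wave effect
(main effect plus the wave-by-season interaction evaluated at that date).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grm import PosteriorDraws, build_design, category_probabilities, season_terms
from .scoring import N_ITEMS

__all__ = ["predict_wave_sums", "seasonal_effect_curve"]


def predict_wave_sums(
    draws: PosteriorDraws,
    responses: pd.DataFrame,
    persons: pd.DataFrame,
    n_draws_use: int = 200,
    seed: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """Posterior-predictive per-wave GHQ-12 sum means and SDs.

    For each retained posterior draw, item responses are simulated for every
    person-wave that is completely observed (mirroring the complete-case
    convention of the observed summaries), summed to the 0-36 score, and
    averaged within wave.  Reported per wave: observed mean/SD and the
    posterior means of the simulated within-wave mean and SD.

    Refuses non-converged draws unless ``force=True``.
    """
    if draws.converged is False and not force:
        raise ValueError(
            "posterior draws failed the convergence gate; pass force=True to override"
        )
    rng = np.random.default_rng(seed)
    meta = draws.meta
    columns = meta["columns"]
    person_index = np.asarray(meta["person_index"])
    item_ids = np.asarray(meta["item_ids"])
    person_pos = {pid: k for k, pid in enumerate(person_index)}

    obs = responses.dropna(subset=["response"])
    counts = obs.groupby(["person_id", "wave"]).size()
    complete_pw = counts[counts == len(item_ids)].index

    n_waves = int(responses["wave"].max()) + 1
    design = build_design(persons, n_waves=n_waves, spec="m5")[columns]

    beta = np.stack([draws.stacked(f"b_{c}") for c in columns], axis=-1)
    theta = draws.stacked("theta")
    log_disc = draws.stacked("log_disc")
    thresholds = draws.stacked("thresholds")
    S = beta.shape[0]
    use = np.linspace(0, S - 1, min(n_draws_use, S)).astype(int)

    rows = []
    for w in range(n_waves):
        pids = [p for (p, wv) in complete_pw if wv == w]
        sw = obs[(obs["wave"] == w) & obs["person_id"].isin(pids)]
        observed_sums = sw.groupby("person_id")["response"].sum()
        if len(pids) == 0:
            continue
        ppos = np.array([person_pos[p] for p in pids])
        row_pos = design.index.get_indexer(
            pd.MultiIndex.from_arrays([pids, [w] * len(pids)])
        )
        X = design.to_numpy(float)[row_pos]
        mean_draws = np.empty(len(use))
        sd_draws = np.empty(len(use))
        for k, s in enumerate(use):
            eta = theta[s, ppos] + X @ beta[s]  # (n_pw,)
            probs = category_probabilities(
                np.repeat(eta[:, None], len(item_ids), axis=1),
                np.broadcast_to(log_disc[s], (len(eta), len(item_ids))),
                np.broadcast_to(
                    thresholds[s], (len(eta),) + thresholds[s].shape
                ),
            )
            cum = np.cumsum(probs, axis=-1)
            u = rng.random(cum.shape[:-1])
            sim = (u[..., None] > cum[..., :-1]).sum(axis=-1)
            sums = sim.sum(axis=1)
            mean_draws[k] = sums.mean()
            sd_draws[k] = sums.std(ddof=1) if len(sums) > 1 else np.nan
        rows.append(
            {
                "wave": w,
                "n_complete": len(pids),
                "observed_mean": float(observed_sums.mean()),
                "observed_sd": float(observed_sums.std(ddof=1)),
                "predicted_mean": float(mean_draws.mean()),
                "predicted_sd": float(np.nanmean(sd_draws)),
                "predicted_mean_mc_sd": float(mean_draws.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def seasonal_effect_curve(
    draws: PosteriorDraws,
    trip_dates,
    waves=(1, 2),
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior total wave effect by trip-return date, with credible bands.

    For each date with day-count ``t`` and each posterior draw, the total
    coefficient of wave ``w`` is ``b_wave{w} + b_wave{w}_cos * cos(2*pi*t/360)
    + b_wave{w}_sin * sin(2*pi*t/360)`` (the sine interaction term is used
    only if present in the fit).  Summaries are the posterior mean and the
    central equal-tailed interval at ``level``.
    """
    meta = draws.meta
    columns = meta["columns"]
    if not any(c.endswith("_cos") for c in columns):
        raise ValueError("model has no wave-by-season interaction terms")
    dates = pd.to_datetime(pd.Series(list(trip_dates))).drop_duplicates().sort_values()
    from .grm import TRIP_ORIGIN

    t_days = (dates - TRIP_ORIGIN).dt.days.to_numpy(float)
    cos_t, sin_t = season_terms(t_days)
    alpha = (1.0 - level) / 2.0
    rows = []
    for w in waves:
        main = draws.stacked(f"b_wave{w}")
        b_cos = draws.stacked(f"b_wave{w}_cos")
        if f"wave{w}_sin" in columns:
            b_sin = draws.stacked(f"b_wave{w}_sin")
        else:
            b_sin = np.zeros_like(main)
        total = (
            main[:, None]
            + b_cos[:, None] * cos_t[None, :]
            + b_sin[:, None] * sin_t[None, :]
        )
        mean = total.mean(axis=0)
        lo = np.quantile(total, alpha, axis=0)
        hi = np.quantile(total, 1.0 - alpha, axis=0)
        for k, d in enumerate(dates):
            rows.append(
                {
                    "wave": w,
                    "trip_return_date": d.date().isoformat(),
                    "t_days": t_days[k],
                    "posterior_mean": mean[k],
                    "ci_lower": lo[k],
                    "ci_upper": hi[k],
                }
            )
    return pd.DataFrame(rows)


def plot_seasonal_curve(curve: pd.DataFrame, path=None):  # pragma: no cover
    """Optional rendering of the per-date effect table (one panel per wave)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    waves = sorted(curve["wave"].unique())
    fig, axes = plt.subplots(1, len(waves), figsize=(5 * len(waves), 4), squeeze=False)
    for ax, w in zip(axes[0], waves):
        sub = curve[curve["wave"] == w]
        x = pd.to_datetime(sub["trip_return_date"])
        ax.plot(x, sub["posterior_mean"], "o", label="posterior mean")
        ax.vlines(x, sub["ci_lower"], sub["ci_upper"], lw=1)
        ax.axhline(0.0, ls="--", c="grey")
        ax.set_title(f"wave {w} total effect by trip return date")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
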