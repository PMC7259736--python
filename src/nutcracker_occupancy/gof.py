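"""Bayesian MacKenzie-Bailey goodness-of-fit for the occupancy model.

The discrepancy is the detection-history chi-square: within each year-stage
stratum, the observed counts of the 8 possible histories are compared with
their expected frequencies under the model (computed from the marginal
unit likelihood), ``T = sum (O - E)^2 / E``; sparse cells (expected < 2)
are pooled into a remainder cell.  In the Bayesian version the statistic is
evaluated per posterior draw on the observed data (``T_obs``) and on a
replicate dataset simulated from that draw's parameters (``T_rep``); the
model fits adequately when the 95% credible interval of ``D = T_rep -
T_obs`` includes 0.  ``P(T_rep >= T_obs)`` is reported as the Bayesian
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .occupancy_mcmc import (
    OccupancyData,
    PosteriorDraws,
    history_probabilities,
)

__all__ = ["GofReport", "mb_statistic", "unit_probabilities", "posterior_predictive_gof"]


@dataclass
class GofReport:
    """Per-draw observed/replicate discrepancies and the fit verdict."""

    t_obs: np.ndarray
    t_rep: np.ndarray
    d_lower95: float
    d_upper95: float
    bayesian_p: float
    adequate: bool

    @property
    def d(self) -> np.ndarray:
        return self.t_rep - self.t_obs

    def to_dict(self) -> dict:
        return {
            "d_lower95": float(self.d_lower95),
            "d_upper95": float(self.d_upper95),
            "bayesian_p": float(self.bayesian_p),
            "adequate": bool(self.adequate),
            "n_draws": int(len(self.t_obs)),
        }


def _pooled_chisq(observed: np.ndarray, expected: np.ndarray, min_expected: float) -> float:
    """Chi-square over history cells with sparse-cell pooling.

    Cells with expected count below ``min_expected`` are merged into one
    remainder cell; a remainder with zero expectation is dropped (it can
    carry no observations under the model).
    """
    keep = expected >= min_expected
    o = list(observed[keep])
    e = list(expected[keep])
    if not keep.all():
        o.append(observed[~keep].sum())
        e.append(expected[~keep].sum())
    o, e = np.asarray(o, dtype=float), np.asarray(e, dtype=float)
    if np.any((e <= 0) & (o > 0)):
        warnings.warn("observed count in a zero-expectation cell dropped", stacklevel=3)
    mask = e > 0
    return float((((o - e) ** 2)[mask] / e[mask]).sum())


def mb_statistic(
    histories: np.ndarray,
    psi: np.ndarray,
    p: np.ndarray,
    strata: np.ndarray | None = None,
    min_expected: float = 2.0,
) -> float:
    """MacKenzie-Bailey chi-square discrepancy.

    Parameters
    ----------
    histories
        ``(n, 3)`` binary detection histories.
    psi, p
        Per-unit occurrence and (count-shared) detection probabilities.
    strata
        Integer stratum label per unit (year-stage cells); a single
        stratum when omitted.  Expected frequencies are accumulated within
        strata from the marginal history probabilities, and cells with
        expected < ``min_expected`` are pooled.
    """
    h = np.asarray(histories)
    psi = np.asarray(psi, dtype=float)
    p = np.asarray(p, dtype=float)
    if strata is None:
        strata = np.zeros(len(h), dtype=int)
    codes = h[:, 0] * 4 + h[:, 1] * 2 + h[:, 2]
    probs = history_probabilities(psi, p)  # (n, 8) marginal probabilities
    total = 0.0
    for s in np.unique(strata):
        idx = strata == s
        observed = np.bincount(codes[idx], minlength=8).astype(float)
        expected = probs[idx].sum(axis=0)
        total += _pooled_chisq(observed, expected, min_expected)
    return total


def unit_probabilities(
    draws: PosteriorDraws, data: OccupancyData, draw_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw, per-unit (psi, p) implied by stored posterior draws.

    Reconstructs the occurrence and detection linear predictors — stage
    intercepts, covariate terms under each draw's selected model, and any
    stored random effects — for the fitted data's units.  Returns arrays of
    shape ``(len(draw_indices), n_units)``.
    """
    X = data.design.X
    stage_of = data.stage_idx
    n = data.n_units
    alpha = draws.stacked("alpha")[draw_indices]          # (d, S)
    beta = draws.stacked("beta")[draw_indices]            # (d, S, K)
    mu_p = draws.stacked("mu_p")[draw_indices]            # (d,)
    d = len(draw_indices)

    # inclusion pattern per draw and stage
    K = X.shape[1]
    S = alpha.shape[1]
    if "model_index" in draws.params:
        cand = draws.meta["candidate_models"]
        terms = draws.meta["terms"]
        columns = draws.meta["columns"]
        midx = draws.stacked("model_index")[draw_indices]  # (d, S)
        masks_by_stage = []
        for s_name in draws.meta["stage_names"]:
            masks = []
            for m in cand[s_name]:
                mask = np.zeros(K, dtype=bool)
                for t in m["terms"]:
                    for c in terms[t]:
                        mask[columns.index(c)] = True
                masks.append(mask)
            masks_by_stage.append(np.array(masks))
        incl = np.empty((d, S, K), dtype=bool)
        for s in range(S):
            incl[:, s, :] = masks_by_stage[s][midx[:, s]]
        beta = np.where(incl, beta, 0.0)

    if "beta_year" in draws.params:
        coef = draws.stacked("beta_year")[draw_indices][:, data.cell_idx, :]
        if "model_index" in draws.params:
            coef = coef * incl[:, stage_of, :]
    else:
        coef = beta[:, stage_of, :]                        # (d, n, K)

    lp_psi = alpha[:, stage_of] + (X[None, :, :] * coef).sum(axis=2)
    if "u_site" in draws.params:
        lp_psi = lp_psi + draws.stacked("u_site")[draw_indices][:, data.site_idx]
    lp_p = np.broadcast_to(mu_p[:, None], (d, n)).copy()
    if "eps" in draws.params:
        lp_p += draws.stacked("eps")[draw_indices][:, data.cell_idx]
    if "eta" in draws.params:
        lp_p += draws.stacked("eta")[draw_indices]
    return expit(lp_psi), expit(lp_p)


def posterior_predictive_gof(
    draws: PosteriorDraws,
    data: OccupancyData,
    n_gof_draws: int = 500,
    min_expected: float = 2.0,
    seed: int = 0,
) -> GofReport:
    """Posterior-predictive MacKenzie-Bailey check.

    For each of up to ``n_gof_draws`` posterior draws (an evenly thinned
    subset), computes ``T_obs`` on the observed histories and ``T_rep`` on
    a replicate simulated from that draw's generative model (latent
    occupancy then three Bernoulli counts).  The verdict is "adequate" iff
    the central 95% interval of ``T_rep - T_obs`` includes 0.

    Raises
    ------
    ValueError
        With fewer than 100 available draws, or degenerate (zero-variance)
        draws.
    """
    total = draws.n_chains * draws.n_draws
    if total < 100:
        raise ValueError(f"too few posterior draws for GOF ({total} < 100)")
    take = min(n_gof_draws, total)
    draw_indices = np.linspace(0, total - 1, take).astype(int)
    psi, p = unit_probabilities(draws, data, draw_indices)
    if float(psi.std()) == 0.0 and float(p.std()) == 0.0:
        raise ValueError("degenerate posterior draws: zero variance in psi and p")
    rng = np.random.default_rng(seed)
    strata = data.cell_idx
    t_obs = np.empty(take)
    t_rep = np.empty(take)
    n = data.n_units
    for j in range(take):
        t_obs[j] = mb_statistic(data.h, psi[j], p[j], strata, min_expected)
        z_rep = rng.random(n) < psi[j]
        h_rep = (rng.random((n, 3)) < (z_rep[:, None] * p[j][:, None])).astype(np.int8)
        t_rep[j] = mb_statistic(h_rep, psi[j], p[j], strata, min_expected)
    d = t_rep - t_obs
    lo, hi = np.percentile(d, [2.5, 97.5])
    return GofReport(
        t_obs=t_obs,
        t_rep=t_rep,
        d_lower95=float(lo),
        d_upper95=float(hi),
        bayesian_p=float((t_rep >= t_obs).mean()),
        adequate=bool(lo <= 0.0 <= hi),
    )
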