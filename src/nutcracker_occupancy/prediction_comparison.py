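"""Occurrence prediction curves, habitat-area thresholds, and comparisons
with previously published cone-crop occurrence models.

Prediction curves evaluate the fitted occurrence model over a grid of one
covariate (original units), holding every other covariate at its mean and
random effects at zero (a typical site), per posterior draw — model-averaged
through the latent model-indicator chain when selection was active — and
summarize the pointwise posterior mean and central 95% credible band.
Thresholds answer the management question "how much cone-bearing whitebark
pine habitat does the landscape need for a >=75% probability of nutcracker
occurrence?" by locating the smallest covariate value whose mean predicted
occurrence reaches the target.

Two fixed published comparator models predict the proportion of survey
time with at least one nutcracker detection from a cone-production index
(the squared log of cone density per hectare): a linear regression
``y = -0.449 + 0.019 x`` and a beta regression
``y = expit(-1.5165 + 0.03883 x)``.  Observed-versus-predicted agreement is
assessed with Spearman rank correlation and a one-tailed Wilcoxon
signed-rank test of underprediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .occupancy_mcmc import PosteriorDraws

__all__ = [
    "PredictionCurve",
    "predict_psi",
    "threshold_area",
    "mckinney_predict",
    "barringer_predict",
    "cone_production_index",
    "comparator_filter",
    "compare_observed_predicted",
]


@dataclass
class PredictionCurve:
    """Occurrence probability along one covariate grid with 95% bounds."""

    covariate: str
    grid: np.ndarray               # original units
    grid_standardized: np.ndarray
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    stage: str
    conditioning: dict
    extrapolated: np.ndarray       # flags grid points outside observed range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "mean": self.mean,
                "lower95": self.lower95,
                "upper95": self.upper95,
                "extrapolated": self.extrapolated,
            }
        )


def _draw_curves(
    draws: PosteriorDraws,
    stage: str,
    covariate: str,
    grid_std: np.ndarray,
    conditioning: Mapping[str, float],
) -> np.ndarray:
    """Per-draw psi over the standardized grid: (n_total_draws, n_grid)."""
    meta = draws.meta
    columns = list(meta["columns"])
    stage_names = list(meta["stage_names"])
    if stage not in stage_names:
        raise ValueError(f"stage {stage!r} not in fitted stages {stage_names}")
    for name in conditioning:
        if name not in columns:
            raise KeyError(f"conditioning references unknown covariate {name!r}")
    s = stage_names.index(stage)
    k_cov = columns.index(covariate)
    alpha = draws.stacked("alpha")[:, s]            # (D,)
    beta = draws.stacked("beta")[:, s, :]           # (D, K)
    if "model_index" in draws.params:
        cand = meta["candidate_models"][stage]
        terms = meta["terms"]
        masks = []
        for m in cand:
            mask = np.zeros(len(columns), dtype=bool)
            for t in m["terms"]:
                for c in terms[t]:
                    mask[columns.index(c)] = True
            masks.append(mask)
        midx = draws.stacked("model_index")[:, s]
        beta = np.where(np.array(masks)[midx], beta, 0.0)
    # fixed covariates: standardized value 0 = their mean unless conditioned
    fixed = np.zeros(len(columns))
    for name, value in conditioning.items():
        fixed[columns.index(name)] = value
    fixed[k_cov] = 0.0
    lp = (
        alpha[:, None]
        + (beta @ fixed)[:, None]
        + beta[:, [k_cov]] * grid_std[None, :]
    )
    return expit(lp)


def predict_psi(
    draws: PosteriorDraws,
    stage: str,
    covariate: str,
    grid: np.ndarray | None = None,
    conditioning: Mapping[str, float] | None = None,
    observed_range: tuple[float, float] | None = None,
    n_grid: int = 200,
) -> PredictionCurve:
    """Posterior occurrence-probability curve along one covariate.

    ``grid`` is in the covariate's original units (defaults to ``n_grid``
    points spanning the observed range recorded in the draws' metadata);
    other covariates are held at their means and random effects at zero.
    ``conditioning`` gives standardized values for covariates to hold at
    non-mean levels — e.g. ``{"cone_density_absent": 1.0}`` for a
    cones-absent prediction.  Grid points outside the observed covariate
    range are flagged as extrapolated.
    """
    meta = draws.meta
    mu, sd = meta["column_stats"][covariate]
    if observed_range is None:
        observed_range = tuple(meta.get("observed_range", {}).get(covariate, (np.nan, np.nan)))
    if grid is None:
        if not np.isfinite(observed_range).all():
            raise ValueError(
                "no grid given and no observed covariate range recorded in draws"
            )
        grid = np.linspace(observed_range[0], observed_range[1], n_grid)
    grid = np.asarray(grid, dtype=float)
    grid_std = (grid - mu) / sd if sd else grid
    conditioning = dict(conditioning or {})
    curves = _draw_curves(draws, stage, covariate, grid_std, conditioning)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    if np.isfinite(observed_range).all():
        extrapolated = (grid < observed_range[0]) | (grid > observed_range[1])
    else:
        extrapolated = np.zeros(len(grid), dtype=bool)
    if extrapolated.any():
        warnings.warn("prediction grid extends beyond the observed covariate range", stacklevel=2)
    return PredictionCurve(
        covariate=covariate,
        grid=grid,
        grid_standardized=grid_std,
        mean=curves.mean(axis=0),
        lower95=lo,
        upper95=hi,
        stage=stage,
        conditioning=conditioning,
        extrapolated=extrapolated,
    )


def threshold_area(curve: PredictionCurve, target: float) -> float | None:
    """Smallest covariate value whose mean predicted occurrence reaches
    ``target``, linearly interpolated between bracketing grid points.

    Returns ``None`` when the curve never reaches the target.  The search
    assumes a monotone mean curve; if the curve crosses the target more
    than once the smallest crossing is returned with a warning.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target probability must lie strictly between 0 and 1")
    mean = curve.mean
    above = mean >= target
    if not above.any():
        return None
    first = int(np.argmax(above))
    crossings = int(((above[1:] != above[:-1])).sum())
    if crossings > 1:
        warnings.warn(
            "prediction curve crosses the target more than once; "
            "returning the smallest crossing",
            stacklevel=2,
        )
    if first == 0:
        return float(curve.grid[0])
    x0, x1 = curve.grid[first - 1], curve.grid[first]
    y0, y1 = mean[first - 1], mean[first]
    return float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))


def cone_production_index(cone_density: np.ndarray, base: str = "natural") -> np.ndarray:
    """Squared log of cone density per hectare (the comparator models'
    predictor).  ``base`` selects natural log (default) or ``"log10"``."""
    x = np.asarray(cone_density, dtype=float)
    if np.any(x <= 0):
        raise ValueError("cone production index requires strictly positive densities")
    logs = np.log(x) if base == "natural" else np.log10(x)
    return logs**2


def mckinney_predict(x: np.ndarray | float) -> np.ndarray | float:
    """Published linear cone-crop model: ``y = -0.449 + 0.019 x``.

    ``x`` is the squared-log cone-production index.  The raw affine value
    is returned unclipped (it can leave [0, 1]); clip separately if a
    proportion is required.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("cone production index must be non-negative")
    out = -0.449 + 0.019 * x
    return float(out) if out.ndim == 0 else out


def barringer_predict(x: np.ndarray | float) -> np.ndarray | float:
    """Published beta-regression cone-crop model:
    ``y = expit(-1.5165 + 0.03883 x)`` — always strictly inside (0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("cone production index must be non-negative")
    out = expit(-1.5165 + 0.03883 * x)
    return float(out) if out.ndim == 0 else out


def comparator_filter(
    units: pd.DataFrame,
    radius_class: str = "infinite",
    date_window: tuple[str, str] = ("07-15", "09-15"),
    cone_column: str = "cone_density",
) -> pd.DataFrame:
    """Apply the comparator studies' data filters to a survey-unit table.

    Keeps infinite-radius surveys with strictly positive cone density and a
    survey date between July 15 and September 15 inclusive (month-day
    window applied within each year).  The same-day cone-count requirement
    is satisfied by construction for synthetic data, where cone counts are
    taken on the survey date.
    """
    df = units.copy()
    keep = df["radius_class"] == radius_class
    keep &= df[cone_column] > 0
    md = pd.to_datetime(df["date"]).dt.strftime("%m-%d")
    keep &= (md >= date_window[0]) & (md <= date_window[1])
    return df.loc[keep]


def compare_observed_predicted(
    observed: np.ndarray, predicted: np.ndarray
) -> dict[str, float]:
    """Spearman correlation and one-tailed Wilcoxon signed-rank comparison.

    Tests whether the comparator model *underpredicts*: the alternative is
    observed > predicted (paired, one-tailed).  Zero differences are
    dropped and ties take mid-ranks (standard signed-rank handling).  With
    every difference zero the test is undefined and reported as NaN.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be paired 1-d vectors")
    if len(observed) < 5:
        raise ValueError("need at least 5 pairs")
    rho, rho_p = stats.spearmanr(observed, predicted)
    diffs = observed - predicted
    if np.all(diffs == 0):
        w, w_p = np.nan, np.nan
    else:
        res = stats.wilcoxon(
            observed, predicted, alternative="greater", zero_method="wilcox"
        )
        w, w_p = float(res.statistic), float(res.pvalue)
    return {
        "n": int(len(observed)),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "wilcoxon_w": w,
        "wilcoxon_p": w_p,
    }
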