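"""Hierarchical single-season occupancy model and Metropolis-within-Gibbs sampler.

Model
-----
Each survey unit *i* (one site-stage-year detection history, three
ten-minute counts) has a latent occupancy (use) state ``z_i ~
Bernoulli(psi_i)`` and, conditional on ``z_i = 1``, three independent
detections ``h_it ~ Bernoulli(p_i)``.  On the logit scale::

    logit psi_i = alpha[stage_i] + u[site_i] + sum_j I[j, stage_i] * beta_j,i * x_ij
    logit p_i   = mu_p + eps[year_i, stage_i] + eta_i

with site effects ``u ~ N(0, sigma_site^2)``, year-stage detection effects
``eps ~ N(0, sigma_p^2)`` around a single hyper-mean ``mu_p``, an
observation-level effect ``eta ~ N(0, sigma_obs^2)`` per survey unit, and —
optionally — year-varying coefficients ``beta_{j,s,y} ~ N(mu_{j,s},
sigma_j^2)`` around covariate-specific hyper-means.  ``I[j, s]`` is the
covariate-inclusion pattern of the current model for stage *s*; when model
selection is active it is driven by a latent model indicator (see
:mod:`nutcracker_occupancy.model_selection`).

Sampling
--------
The latent ``z`` is sampled from its Bernoulli full conditional (data
augmentation), which makes every other full conditional a Bernoulli GLM
update and the model-indicator full conditional a cheap categorical draw.
Location parameters use adaptive random-walk Metropolis (scales tuned
during burn-in only, then frozen); standard deviations are updated on the
log scale against their Uniform(0, upper) priors; coefficients excluded
under the current model evolve under their prior (prior-as-pseudoprior),
preserving between-model mixing.  The marginal (z-integrated) unit
likelihood is retained for oracles and goodness-of-fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import model_selection as _msel
from .data_model import DesignMatrix, Stage

__all__ = [
    "Priors",
    "MCMCSettings",
    "ModelConfig",
    "OccupancyData",
    "PosteriorDraws",
    "unit_likelihood",
    "history_probabilities",
    "build_occupancy_data",
    "run_mcmc",
    "convergence_diagnostics",
]


# --------------------------------------------------------------------------
# configuration containers


@dataclass(frozen=True)
class Priors:
    """Diffuse priors for all hyperparameters.

    ``intercept_sd`` — Normal(0, sd^2) for logit-scale intercepts (stage
    occurrence intercepts and the detection hyper-mean).  ``coef_sd`` —
    Normal(0, sd^2) for covariate coefficient hyper-means; covariates are
    standardized, so 2.5 is weakly informative on the logit scale while
    keeping Bayes-factor penalties for spurious terms moderate.
    ``sd_upper`` — Uniform(0, upper) for every hierarchical standard
    deviation.
    """

    intercept_sd: float = 10.0
    coef_sd: float = 2.5
    sd_upper: float = 10.0


@dataclass(frozen=True)
class MCMCSettings:
    """Chain geometry.  Defaults are desk-scale (3 chains x 4,000 draws,
    1,000 burn-in); :meth:`paper_scale` gives the original analysis scale
    (3 x 60,000 with 20,000 burn-in, thin 1)."""

    n_chains: int = 3
    n_iter: int = 4000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "MCMCSettings":
        return cls(n_chains=3, n_iter=60_000, n_burnin=20_000, thin=1, seed=seed)

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass(frozen=True)
class ModelConfig:
    """Which random-effect layers are active.

    The full study model uses all four layers; simpler layouts (e.g. a
    single stage-year of simulated data) turn layers off, which fixes the
    corresponding sd at 0 and drops the effects.
    """

    site_effect: bool = True
    year_stage_detection_effect: bool = True
    observation_effect: bool = True
    year_varying_coefficients: bool = True


# --------------------------------------------------------------------------
# data container


@dataclass
class OccupancyData:
    """Aligned arrays for one radius class: detection histories plus design."""

    h: np.ndarray                    # (n, 3) binary
    stage_idx: np.ndarray            # (n,) into stage_names
    year_idx: np.ndarray             # (n,) into year_labels
    site_idx: np.ndarray             # (n,) into site_labels
    cell_idx: np.ndarray             # (n,) into cell_labels (year-stage cells)
    design: DesignMatrix
    stage_names: list[str]
    year_labels: list[int]
    site_labels: list[str]
    cell_labels: list[tuple[int, str]]

    @property
    def n_units(self) -> int:
        return self.h.shape[0]

    def __post_init__(self) -> None:
        if self.n_units == 0:
            raise ValueError("occupancy data is empty")
        if self.h.shape != (self.n_units, 3) or not np.isin(self.h, (0, 1)).all():
            raise ValueError("histories must be an (n, 3) binary array")
        if self.design.X.shape[0] != self.n_units:
            raise ValueError("design matrix rows do not match histories")


def build_occupancy_data(units: pd.DataFrame, design: DesignMatrix) -> OccupancyData:
    """Assemble sampler arrays from a per-unit table.

    ``units`` needs columns ``site_id, year, stage, count1..count3``, one
    row per detection-history unit, aligned row-for-row with ``design``.
    """
    for col in ("site_id", "year", "stage", "count1", "count2", "count3"):
        if col not in units.columns:
            raise ValueError(f"units table missing column {col!r}")
    stage_values = [s.value if isinstance(s, Stage) else str(s) for s in units["stage"]]
    stage_names = [s.value for s in Stage if s.value in set(stage_values)]
    years = sorted(set(int(y) for y in units["year"]))
    sites = list(dict.fromkeys(str(s) for s in units["site_id"]))
    stage_idx = np.array([stage_names.index(s) for s in stage_values])
    year_idx = np.array([years.index(int(y)) for y in units["year"]])
    site_idx = np.array([sites.index(str(s)) for s in units["site_id"]])
    cells = list(dict.fromkeys(zip((int(y) for y in units["year"]), stage_values)))
    cell_idx = np.array(
        [cells.index((int(y), s)) for y, s in zip(units["year"], stage_values)]
    )
    h = units[["count1", "count2", "count3"]].to_numpy(dtype=np.int8)
    return OccupancyData(
        h=h,
        stage_idx=stage_idx,
        year_idx=year_idx,
        site_idx=site_idx,
        cell_idx=cell_idx,
        design=design,
        stage_names=stage_names,
        year_labels=years,
        site_labels=sites,
        cell_labels=cells,
    )


# --------------------------------------------------------------------------
# marginal unit likelihood (kept for oracles and goodness-of-fit)


def unit_likelihood(psi, p, h) -> np.ndarray | float:
    """Marginal likelihood of one detection history.

    ``psi * prod_t p_t^h_t (1-p_t)^(1-h_t) + (1-psi) * 1[h == (0,0,0)]`` —
    the occupancy state is integrated out.  ``p`` may be a scalar (shared
    across the three counts) or a length-3 vector; broadcasting over leading
    axes is supported.
    """
    psi = np.asarray(psi, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h)
    if np.any((psi < 0) | (psi > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("psi and p must lie in [0, 1]")
    if h.shape[-1] != 3 or not np.isin(h, (0, 1)).all():
        raise ValueError("history must be a binary triple")
    if p.ndim == 0 or p.shape[-1] != 3:
        p = np.broadcast_to(p[..., None] if p.ndim else p, h.shape)
    cond = np.prod(np.where(h == 1, p, 1.0 - p), axis=-1)
    all_zero = (h.sum(axis=-1) == 0).astype(float)
    out = psi * cond + (1.0 - psi) * all_zero
    return float(out) if out.ndim == 0 else out


_ALL_HISTORIES = np.array(
    [[(i >> 2) & 1, (i >> 1) & 1, i & 1] for i in range(8)], dtype=np.int8
)


def history_probabilities(psi: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Marginal probabilities of the 8 possible histories.

    ``psi`` and ``p`` are per-unit vectors (detection shared across the
    three counts); returns an ``(n, 8)`` array of probabilities ordered by
    the binary encoding of the history (0,0,0) ... (1,1,1).
    """
    psi = np.asarray(psi, dtype=float)[:, None]
    p = np.asarray(p, dtype=float)[:, None]
    k = _ALL_HISTORIES.sum(axis=1)[None, :]
    probs = psi * p**k * (1.0 - p) ** (3 - k)
    probs[:, 0] += (1.0 - psi[:, 0])
    return probs


# --------------------------------------------------------------------------
# posterior draws container


@dataclass
class PosteriorDraws:
    """Labeled MCMC draws, shaped ``(n_chains, n_draws, ...)`` per parameter.

    ``coords`` labels trailing axes (stage names, design columns, site ids,
    ...); ``meta`` carries the settings, priors, candidate-set and
    standardization metadata needed to reuse the draws for prediction and
    goodness-of-fit without the original fitting session.
    """

    params: dict[str, np.ndarray]
    coords: dict[str, list]
    meta: dict

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains concatenated along axis 0."""
        a = self.params[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def flat(self) -> dict[str, np.ndarray]:
        """Scalar-expanded view: one (chains, draws) array per labeled entry."""
        out: dict[str, np.ndarray] = {}
        for name, a in self.params.items():
            if a.ndim == 2:
                out[name] = a
                continue
            labels = self.coords.get(name)
            flatted = a.reshape(a.shape[0], a.shape[1], -1)
            for j in range(flatted.shape[2]):
                label = labels[j] if labels is not None else j
                out[f"{name}[{label}]"] = flatted[:, :, j]
        return out

    def summary(self, name: str) -> pd.DataFrame:
        """Posterior mean and central 95% credible interval per element."""
        rows = []
        for label, a in self.flat().items():
            if not label.startswith(name):
                continue
            v = a.reshape(-1)
            lo, hi = np.percentile(v, [2.5, 97.5])
            rows.append((label, float(v.mean()), float(lo), float(hi)))
        return pd.DataFrame(rows, columns=["parameter", "mean", "lower95", "upper95"])

    def save(self, directory) -> None:
        """Write draws as columnar CSV plus YAML metadata."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = self.flat()
        n_chains, n_draws = self.n_chains, self.n_draws
        table = {
            "chain": np.repeat(np.arange(n_chains), n_draws),
            "draw": np.tile(np.arange(n_draws), n_chains),
        }
        for label, a in flat.items():
            table[label] = a.reshape(-1)
        pd.DataFrame(table).to_csv(directory / "draws.csv", index=False)
        meta = dict(self.meta)
        meta["param_shapes"] = {k: list(v.shape[2:]) for k, v in self.params.items()}
        meta["coords"] = {k: list(v) for k, v in self.coords.items()}
        with open(directory / "meta.yaml", "w") as fh:
            yaml.safe_dump(_yaml_ready(meta), fh, default_flow_style=None)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        from pathlib import Path

        directory = Path(directory)
        df = pd.read_csv(directory / "draws.csv")
        with open(directory / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        shapes = meta.pop("param_shapes")
        coords = {k: list(v) for k, v in meta.pop("coords").items()}
        n_chains = int(df["chain"].max()) + 1
        n_draws = len(df) // n_chains
        params: dict[str, np.ndarray] = {}
        for name, shape in shapes.items():
            if not shape:
                params[name] = df[name].to_numpy().reshape(n_chains, n_draws)
                continue
            labels = coords.get(name)
            size = int(np.prod(shape))
            cols = [f"{name}[{labels[j] if labels else j}]" for j in range(size)]
            a = df[cols].to_numpy().reshape(n_chains, n_draws, *shape)
            params[name] = a
        return cls(params=params, coords=coords, meta=meta)

    def to_inference_data(self):
        """Convert to an :mod:`arviz` ``InferenceData`` (posterior group)."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.params.items()})


def _yaml_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _yaml_ready(obj.tolist())
    return obj


# --------------------------------------------------------------------------
# sampler internals


def _bern_loglik(z: np.ndarray, lp: np.ndarray) -> np.ndarray:
    """Pointwise Bernoulli log-likelihood with logit-scale linear predictor."""
    return z * lp - np.logaddexp(0.0, lp)


def _det_loglik(k: np.ndarray, lp: np.ndarray) -> np.ndarray:
    """Binomial(3) detection log-likelihood given occupancy (k detections)."""
    return k * lp - 3.0 * np.logaddexp(0.0, lp)


class _AdaptiveScale:
    """Random-walk proposal scale, tuned in batches during burn-in only."""

    def __init__(self, size=None, init: float = 0.3, target: float = 0.44):
        self.log_scale = np.full(size, np.log(init)) if size else np.log(init)
        self.target = target
        self.accepted = np.zeros(size) if size else 0.0
        self.tried = 0
        self.batch = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, accepted) -> None:
        self.accepted = self.accepted + accepted
        self.tried += 1

    def adapt(self) -> None:
        if self.tried == 0:
            return
        self.batch += 1
        rate = self.accepted / self.tried
        step = min(0.1, 1.0 / np.sqrt(self.batch))
        self.log_scale = self.log_scale + np.where(rate > self.target, step, -step)
        self.accepted = np.zeros_like(self.accepted) if np.ndim(self.accepted) else 0.0
        self.tried = 0


def _normalize_model_arg(
    data: OccupancyData,
    model: Mapping[str, Sequence[str]] | Sequence[str] | None,
) -> dict[str, tuple[str, ...]]:
    terms = list(data.design.terms)
    if model is None:
        return {s: tuple(terms) for s in data.stage_names}
    if not isinstance(model, Mapping):
        return {s: tuple(model) for s in data.stage_names}
    out = {}
    for s in data.stage_names:
        out[s] = tuple(model.get(s, ()))
    return out


def _term_mask(design: DesignMatrix, terms: Sequence[str]) -> np.ndarray:
    mask = np.zeros(len(design.columns), dtype=bool)
    for t in terms:
        mask[design.term_column_indices(t)] = True
    return mask


def run_mcmc(
    data: OccupancyData,
    settings: MCMCSettings = MCMCSettings(),
    priors: Priors = Priors(),
    config: ModelConfig = ModelConfig(),
    model: Mapping[str, Sequence[str]] | Sequence[str] | None = None,
    selection: "_msel.CandidateModelSet | _msel.ScreeningSpec | None" = None,
    store_random_effects: bool = True,
) -> PosteriorDraws:
    """Draw from the joint posterior of the hierarchical occupancy model.

    Parameters
    ----------
    model
        Fixed covariate-inclusion pattern: term names per stage (or one
        list for all stages).  Ignored when ``selection`` is given.
    selection
        A :class:`~nutcracker_occupancy.model_selection.CandidateModelSet`
        activates the latent model indicator (cross-product selection); a
        :class:`~nutcracker_occupancy.model_selection.ScreeningSpec`
        activates independent per-term inclusion indicators with
        Bernoulli(0.5) priors (global screening).
    store_random_effects
        Keep per-site/per-cell/per-unit effect draws (needed for
        goodness-of-fit on fitted data).

    Returns
    -------
    PosteriorDraws
        Identical seeds and settings give bitwise-identical draws.
    """
    design = data.design
    n = data.n_units
    K = len(design.columns)
    S = len(data.stage_names)
    Y = len(data.year_labels)
    n_sites = len(data.site_labels)
    n_cells = len(data.cell_labels)
    X = design.X
    h = data.h
    k_det = h.sum(axis=1).astype(float)
    det_any = k_det > 0
    stage_of = data.stage_idx
    site_of = data.site_idx
    cell_of = data.cell_idx
    cell_stage = np.array(
        [data.stage_names.index(s) for _, s in data.cell_labels]
    )
    stage_units = [np.flatnonzero(stage_of == s) for s in range(S)]
    cell_units = [np.flatnonzero(cell_of == c) for c in range(n_cells)]

    year_varying = config.year_varying_coefficients and Y > 1

    # selection bookkeeping
    selection_mode = None
    candidate_masks: list[np.ndarray] | None = None
    screen_terms: list[list[str]] | None = None
    if selection is not None:
        if isinstance(selection, _msel.CandidateModelSet):
            selection_mode = "indicator"
            candidate_masks = []
            for s in data.stage_names:
                models = selection.models_for(s)
                candidate_masks.append(
                    np.array([_term_mask(design, m.terms) for m in models])
                )
        elif isinstance(selection, _msel.ScreeningSpec):
            selection_mode = "screen"
            screen_terms = [list(selection.terms_for(s)) for s in data.stage_names]
        else:
            raise TypeError(f"unsupported selection argument: {selection!r}")
        fixed_masks = None
    else:
        fixed = _normalize_model_arg(data, model)
        fixed_masks = np.array(
            [_term_mask(design, fixed[s]) for s in data.stage_names]
        )

    # which columns can ever enter, per stage (drives coefficient updates)
    if selection_mode == "indicator":
        ever = np.array([m.any(axis=0) for m in candidate_masks])
    elif selection_mode == "screen":
        ever = np.array(
            [_term_mask(design, screen_terms[s]) for s in range(S)]
        )
    else:
        ever = fixed_masks.copy()

    n_draws = settings.n_draws
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)

    out: dict[str, np.ndarray] = {
        "alpha": np.empty((settings.n_chains, n_draws, S)),
        "beta": np.empty((settings.n_chains, n_draws, S, K)),
        "mu_p": np.empty((settings.n_chains, n_draws)),
        "sigma_site": np.empty((settings.n_chains, n_draws)),
        "sigma_p": np.empty((settings.n_chains, n_draws)),
        "sigma_obs": np.empty((settings.n_chains, n_draws)),
    }
    if year_varying:
        out["beta_year"] = np.empty((settings.n_chains, n_draws, n_cells, K))
        out["sigma_beta"] = np.empty((settings.n_chains, n_draws, K))
    if store_random_effects:
        if config.site_effect:
            out["u_site"] = np.empty((settings.n_chains, n_draws, n_sites))
        if config.year_stage_detection_effect:
            out["eps"] = np.empty((settings.n_chains, n_draws, n_cells))
        if config.observation_effect:
            out["eta"] = np.empty((settings.n_chains, n_draws, n))
    if selection_mode == "indicator":
        out["model_index"] = np.empty((settings.n_chains, n_draws, S), dtype=np.int64)
    if selection_mode == "screen":
        out["incl"] = np.empty(
            (settings.n_chains, n_draws, S, max(len(t) for t in screen_terms) or 1),
            dtype=np.int8,
        )

    for chain in range(settings.n_chains):
        rng = np.random.default_rng(seeds[chain])

        # --- initial state
        alpha = rng.normal(0.0, 0.5, S)
        beta = np.zeros((S, K))
        beta_cell = np.zeros((n_cells, K)) if year_varying else None
        sigma_beta = np.full(K, 0.25)
        u = np.zeros(n_sites)
        sigma_site = 0.25 if config.site_effect else 0.0
        mu_p = rng.normal(0.0, 0.5)
        eps = np.zeros(n_cells)
        sigma_p = 0.25 if config.year_stage_detection_effect else 0.0
        eta = np.zeros(n)
        sigma_obs = 0.25 if config.observation_effect else 0.0
        z = det_any | (rng.random(n) < 0.5)
        if selection_mode == "indicator":
            model_idx = np.zeros(S, dtype=np.int64)
            incl = np.array([candidate_masks[s][0] for s in range(S)])
        elif selection_mode == "screen":
            incl = ever.copy()
            term_state = [
                np.ones(len(screen_terms[s]), dtype=bool) for s in range(S)
            ]
        else:
            incl = fixed_masks.copy()

        # adaptive proposal scales
        sc_alpha = _AdaptiveScale(S, init=0.3)
        sc_beta = _AdaptiveScale((S, K), init=0.3)
        sc_beta_cell = _AdaptiveScale((n_cells, K), init=0.3) if year_varying else None
        sc_u = _AdaptiveScale(n_sites, init=0.5)
        sc_mu_p = _AdaptiveScale(init=0.2)
        sc_eps = _AdaptiveScale(n_cells, init=0.4)
        sc_eta = _AdaptiveScale(n, init=0.8)
        sc_sd = {name: _AdaptiveScale(init=0.4) for name in ("site", "p", "obs")}
        sc_sigma_beta = _AdaptiveScale(K, init=0.4)

        def coef_rows() -> np.ndarray:
            """(n, K) effective coefficient per unit (inclusion applied)."""
            rows = beta_cell[cell_of] if year_varying else beta[stage_of]
            return rows * incl[stage_of]

        def occ_lp(idx=None) -> np.ndarray:
            i = slice(None) if idx is None else idx
            lp = alpha[stage_of[i]] + (X[i] * coef_rows()[i]).sum(axis=1)
            if config.site_effect:
                lp = lp + u[site_of[i]]
            return lp

        def _det_lp(idx=None) -> np.ndarray:
            i = slice(None) if idx is None else idx
            lp = mu_p + np.zeros(n)[i]
            if config.year_stage_detection_effect:
                lp = lp + eps[cell_of[i]]
            if config.observation_effect:
                lp = lp + eta[i]
            return lp

        keep = 0
        for it in range(settings.n_iter):
            adapting = it < settings.n_burnin

            # ---- latent occupancy state
            lp_occ = occ_lp()
            psi = expit(lp_occ)
            p = expit(_det_lp())
            q0 = (1.0 - p) ** 3
            num = psi * q0
            pz = num / (num + (1.0 - psi))
            z = det_any | (rng.random(n) < pz)
            zf = z.astype(float)

            # ---- stage intercepts
            lp_occ = occ_lp()
            prop = rng.normal(0.0, 1.0, S) * sc_alpha.scale
            acc = np.zeros(S, dtype=bool)
            for s in range(S):
                idx = stage_units[s]
                cur = lp_occ[idx]
                new = cur + prop[s]
                dll = (_bern_loglik(zf[idx], new) - _bern_loglik(zf[idx], cur)).sum()
                dll += (alpha[s] ** 2 - (alpha[s] + prop[s]) ** 2) / (
                    2.0 * priors.intercept_sd**2
                )
                if np.log(rng.random()) < dll:
                    alpha[s] += prop[s]
                    lp_occ[idx] = new
                    acc[s] = True
            sc_alpha.update(acc)

            # ---- coefficients
            if year_varying:
                # year-stage-level coefficients around stage hyper-means
                acc_c = np.zeros((n_cells, K), dtype=bool)
                for c in range(n_cells):
                    s = cell_stage[c]
                    idx = cell_units[c]
                    for k in np.flatnonzero(ever[s]):
                        if not incl[s, k]:
                            beta_cell[c, k] = rng.normal(beta[s, k], sigma_beta[k])
                            continue
                        step = rng.normal(0.0, sc_beta_cell.scale[c, k])
                        cur = lp_occ[idx]
                        new = cur + X[idx, k] * step
                        dll = (
                            _bern_loglik(zf[idx], new) - _bern_loglik(zf[idx], cur)
                        ).sum()
                        b0, b1 = beta_cell[c, k], beta_cell[c, k] + step
                        m = beta[s, k]
                        dll += ((b0 - m) ** 2 - (b1 - m) ** 2) / (
                            2.0 * sigma_beta[k] ** 2
                        )
                        if np.log(rng.random()) < dll:
                            beta_cell[c, k] = b1
                            lp_occ[idx] = new
                            acc_c[c, k] = True
                sc_beta_cell.update(acc_c)
                # conjugate hyper-mean update, then sd of year effects
                for s in range(S):
                    cells_s = np.flatnonzero(cell_stage == s)
                    for k in np.flatnonzero(ever[s]):
                        m = len(cells_s)
                        prec = m / sigma_beta[k] ** 2 + 1.0 / priors.coef_sd**2
                        mean = beta_cell[cells_s, k].sum() / sigma_beta[k] ** 2 / prec
                        beta[s, k] = rng.normal(mean, 1.0 / np.sqrt(prec))
                acc_sb = np.zeros(K, dtype=bool)
                for k in range(K):
                    if not ever[:, k].any():
                        continue
                    new_sd = sigma_beta[k] * np.exp(
                        rng.normal(0.0, sc_sigma_beta.scale[k])
                    )
                    if new_sd < priors.sd_upper:
                        resid = beta_cell[:, k] - beta[cell_stage, k]
                        dll = (
                            -n_cells * np.log(new_sd)
                            - (resid**2).sum() / (2 * new_sd**2)
                        ) - (
                            -n_cells * np.log(sigma_beta[k])
                            - (resid**2).sum() / (2 * sigma_beta[k] ** 2)
                        )
                        dll += np.log(new_sd) - np.log(sigma_beta[k])  # log-scale Jacobian
                        if np.log(rng.random()) < dll:
                            sigma_beta[k] = new_sd
                            acc_sb[k] = True
                sc_sigma_beta.update(acc_sb)
            else:
                acc_b = np.zeros((S, K), dtype=bool)
                for s in range(S):
                    idx = stage_units[s]
                    for k in np.flatnonzero(ever[s]):
                        if not incl[s, k]:
                            beta[s, k] = rng.normal(0.0, priors.coef_sd)
                            continue
                        step = rng.normal(0.0, sc_beta.scale[s, k])
                        cur = lp_occ[idx]
                        new = cur + X[idx, k] * step
                        dll = (
                            _bern_loglik(zf[idx], new) - _bern_loglik(zf[idx], cur)
                        ).sum()
                        b0, b1 = beta[s, k], beta[s, k] + step
                        dll += (b0**2 - b1**2) / (2.0 * priors.coef_sd**2)
                        if np.log(rng.random()) < dll:
                            beta[s, k] = b1
                            lp_occ[idx] = new
                            acc_b[s, k] = True
                sc_beta.update(acc_b)

            # ---- site effects
            if config.site_effect:
                prop_u = rng.normal(0.0, 1.0, n_sites) * sc_u.scale
                cur = lp_occ
                new = cur + prop_u[site_of]
                dll_units = _bern_loglik(zf, new) - _bern_loglik(zf, cur)
                dll_site = np.bincount(site_of, weights=dll_units, minlength=n_sites)
                dll_site += (u**2 - (u + prop_u) ** 2) / (2.0 * sigma_site**2)
                acc_u = np.log(rng.random(n_sites)) < dll_site
                u = u + np.where(acc_u, prop_u, 0.0)
                lp_occ = occ_lp()
                sc_u.update(acc_u)
                # sigma_site
                new_sd = sigma_site * np.exp(rng.normal(0.0, sc_sd["site"].scale))
                acc_s = False
                if new_sd < priors.sd_upper:
                    ssq = (u**2).sum()
                    dll = (-n_sites * np.log(new_sd) - ssq / (2 * new_sd**2)) - (
                        -n_sites * np.log(sigma_site) - ssq / (2 * sigma_site**2)
                    )
                    dll += np.log(new_sd) - np.log(sigma_site)
                    if np.log(rng.random()) < dll:
                        sigma_site = new_sd
                        acc_s = True
                sc_sd["site"].update(acc_s)

            # ---- detection parameters (occupied units only carry information)
            occ_idx = np.flatnonzero(z)
            k_occ = k_det[occ_idx]
            lp_det_occ = _det_lp(occ_idx)

            step = rng.normal(0.0, sc_mu_p.scale)
            dll = (_det_loglik(k_occ, lp_det_occ + step) - _det_loglik(k_occ, lp_det_occ)).sum()
            dll += (mu_p**2 - (mu_p + step) ** 2) / (2.0 * priors.intercept_sd**2)
            acc_m = np.log(rng.random()) < dll
            if acc_m:
                mu_p += step
                lp_det_occ = lp_det_occ + step
            sc_mu_p.update(acc_m)

            if config.year_stage_detection_effect:
                prop_e = rng.normal(0.0, 1.0, n_cells) * sc_eps.scale
                new = lp_det_occ + prop_e[cell_of[occ_idx]]
                dll_units = _det_loglik(k_occ, new) - _det_loglik(k_occ, lp_det_occ)
                dll_cell = np.bincount(
                    cell_of[occ_idx], weights=dll_units, minlength=n_cells
                )
                dll_cell += (eps**2 - (eps + prop_e) ** 2) / (2.0 * sigma_p**2)
                acc_e = np.log(rng.random(n_cells)) < dll_cell
                eps = eps + np.where(acc_e, prop_e, 0.0)
                lp_det_occ = _det_lp(occ_idx)
                sc_eps.update(acc_e)
                new_sd = sigma_p * np.exp(rng.normal(0.0, sc_sd["p"].scale))
                acc_s = False
                if new_sd < priors.sd_upper:
                    ssq = (eps**2).sum()
                    dll = (-n_cells * np.log(new_sd) - ssq / (2 * new_sd**2)) - (
                        -n_cells * np.log(sigma_p) - ssq / (2 * sigma_p**2)
                    )
                    dll += np.log(new_sd) - np.log(sigma_p)
                    if np.log(rng.random()) < dll:
                        sigma_p = new_sd
                        acc_s = True
                sc_sd["p"].update(acc_s)

            if config.observation_effect:
                # unoccupied units: eta has no likelihood, Gibbs from prior
                eta = np.where(
                    z, eta, rng.normal(0.0, sigma_obs, n)
                )
                prop_h = rng.normal(0.0, 1.0, n) * sc_eta.scale
                dll_all = np.zeros(n)
                new = lp_det_occ + prop_h[occ_idx]
                dll_all[occ_idx] = _det_loglik(k_occ, new) - _det_loglik(
                    k_occ, lp_det_occ
                )
                dll_all += (eta**2 - (eta + prop_h) ** 2) / (2.0 * sigma_obs**2)
                acc_h = np.log(rng.random(n)) < dll_all
                acc_h &= z  # only MH-update occupied units
                eta = eta + np.where(acc_h, prop_h, 0.0)
                lp_det_occ = _det_lp(occ_idx)
                sc_eta.update(acc_h | ~z)
                new_sd = sigma_obs * np.exp(rng.normal(0.0, sc_sd["obs"].scale))
                acc_s = False
                if new_sd < priors.sd_upper:
                    ssq = (eta**2).sum()
                    dll = (-n * np.log(new_sd) - ssq / (2 * new_sd**2)) - (
                        -n * np.log(sigma_obs) - ssq / (2 * sigma_obs**2)
                    )
                    dll += np.log(new_sd) - np.log(sigma_obs)
                    if np.log(rng.random()) < dll:
                        sigma_obs = new_sd
                        acc_s = True
                sc_sd["obs"].update(acc_s)

            # ---- latent model indicator / inclusion indicators
            if selection_mode == "indicator":
                coefs = beta_cell[cell_of] if year_varying else beta[stage_of]
                for s in range(S):
                    masks = candidate_masks[s]
                    if len(masks) == 1:
                        model_idx[s] = 0
                        incl[s] = masks[0]
                        continue
                    idx = stage_units[s]
                    base = alpha[s] + (u[site_of[idx]] if config.site_effect else 0.0)
                    contrib = X[idx] * coefs[idx]
                    lls = np.empty(len(masks))
                    for m, mask in enumerate(masks):
                        lp_m = base + contrib[:, mask].sum(axis=1)
                        lls[m] = _bern_loglik(zf[idx], lp_m).sum()
                    model_idx[s] = _msel.categorical_draw(
                        lls + np.log(1.0 / len(masks)), rng
                    )
                    incl[s] = masks[model_idx[s]]
                lp_occ = occ_lp()
            elif selection_mode == "screen":
                coefs = beta_cell[cell_of] if year_varying else beta[stage_of]
                for s in range(S):
                    terms = screen_terms[s]
                    if not terms:
                        continue
                    idx = stage_units[s]
                    contrib = X[idx] * coefs[idx]
                    for t, term in enumerate(terms):
                        cols = design.term_column_indices(term)
                        others = incl[s].copy()
                        others[cols] = False
                        base = (
                            alpha[s]
                            + (u[site_of[idx]] if config.site_effect else 0.0)
                            + contrib[:, others].sum(axis=1)
                        )
                        term_contrib = contrib[:, cols].sum(axis=1)
                        ll_on = _bern_loglik(zf[idx], base + term_contrib).sum()
                        ll_off = _bern_loglik(zf[idx], base).sum()
                        # Bernoulli(0.5) prior on inclusion -> prior odds 1
                        p_on = 1.0 / (1.0 + np.exp(np.clip(ll_off - ll_on, -700, 700)))
                        state = rng.random() < p_on
                        term_state[s][t] = state
                        incl[s, cols] = state
                lp_occ = occ_lp()

            # ---- adaptation bookkeeping
            if adapting and (it + 1) % 50 == 0:
                for sc in (
                    sc_alpha,
                    sc_beta,
                    sc_u,
                    sc_mu_p,
                    sc_eps,
                    sc_eta,
                    sc_sigma_beta,
                    *sc_sd.values(),
                    *( [sc_beta_cell] if year_varying else [] ),
                ):
                    sc.adapt()

            # ---- store
            if it >= settings.n_burnin and (it - settings.n_burnin) % settings.thin == 0:
                out["alpha"][chain, keep] = alpha
                out["beta"][chain, keep] = beta
                out["mu_p"][chain, keep] = mu_p
                out["sigma_site"][chain, keep] = sigma_site
                out["sigma_p"][chain, keep] = sigma_p
                out["sigma_obs"][chain, keep] = sigma_obs
                if year_varying:
                    out["beta_year"][chain, keep] = beta_cell
                    out["sigma_beta"][chain, keep] = sigma_beta
                if store_random_effects:
                    if config.site_effect:
                        out["u_site"][chain, keep] = u
                    if config.year_stage_detection_effect:
                        out["eps"][chain, keep] = eps
                    if config.observation_effect:
                        out["eta"][chain, keep] = eta
                if selection_mode == "indicator":
                    out["model_index"][chain, keep] = model_idx
                if selection_mode == "screen":
                    for s in range(S):
                        out["incl"][chain, keep, s, : len(screen_terms[s])] = term_state[s]
                keep += 1
        keep = 0

    coords = {
        "alpha": list(data.stage_names),
        "beta": [f"{s},{c}" for s in data.stage_names for c in design.columns],
        "u_site": list(data.site_labels),
        "eps": [f"{y},{s}" for y, s in data.cell_labels],
        "eta": list(range(n)),
        "beta_year": [
            f"{y},{s},{c}" for y, s in data.cell_labels for c in design.columns
        ],
        "sigma_beta": list(design.columns),
        "model_index": list(data.stage_names),
    }
    meta = {
        "stage_names": list(data.stage_names),
        "year_labels": list(data.year_labels),
        "cell_labels": [list(c) for c in data.cell_labels],
        "columns": list(design.columns),
        "terms": {k: list(v) for k, v in design.terms.items()},
        "column_stats": {k: list(v) for k, v in design.column_stats.items()},
        "observed_range": {k: list(v) for k, v in design.column_ranges.items()},
        "settings": asdict(settings),
        "priors": asdict(priors),
        "config": asdict(config),
        "selection_mode": selection_mode,
    }
    if selection_mode == "indicator":
        meta["candidate_models"] = {
            s: [{"name": m.name, "terms": list(m.terms)} for m in selection.models_for(s)]
            for s in data.stage_names
        }
    if selection_mode == "screen":
        meta["screen_terms"] = {
            s: list(selection.terms_for(s)) for s in data.stage_names
        }
        coords["incl"] = [
            f"{s},{t}"
            for s_i, s in enumerate(data.stage_names)
            for t in range(out["incl"].shape[3])
        ]
    out_params = {k: v for k, v in out.items()}
    return PosteriorDraws(params=out_params, coords=coords, meta=meta)


# --------------------------------------------------------------------------
# diagnostics


def convergence_diagnostics(draws: PosteriorDraws, threshold: float = 1.1) -> pd.DataFrame:
    """Split-R-hat and effective sample size per scalar parameter.

    Returns a table with columns ``parameter, rhat, ess, flagged``;
    parameters whose R-hat exceeds ``threshold`` (or is undefined, e.g. a
    constant chain) are flagged.  With fewer than two chains the
    diagnostics are marked unavailable (``rhat`` all-NaN, everything
    flagged).
    """
    import arviz as az

    flat = draws.flat()
    rows = []
    if draws.n_chains < 2:
        for name in flat:
            rows.append((name, np.nan, np.nan, True))
        df = pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged"])
        df.attrs["available"] = False
        return df
    for name, a in flat.items():
        if np.allclose(a, a.reshape(-1)[0]):
            rows.append((name, np.nan, np.nan, True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(az.rhat(az.convert_to_dataset(a))["x"].values)
            e = float(az.ess(az.convert_to_dataset(a))["x"].values)
        rows.append((name, r, e, bool(np.isnan(r) or r > threshold)))
    df = pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged"])
    df.attrs["available"] = True
    return df
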