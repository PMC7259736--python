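"""Cross-product Bayesian model selection and inclusion-probability screening.

Two selection mechanisms operate on the occupancy model's occurrence
covariates:

* **Global screening** (phase 1): every candidate covariate term carries an
  independent binary inclusion indicator with a Bernoulli(0.5) prior,
  entering the linear predictor as ``I_j * beta_j * x_j`` (Kuo-Mallick
  product parameterization).  Covariates whose posterior inclusion
  probability ``P(I_j = 1 | y)`` is <= 0.5 are dropped (the
  Barbieri-Berger median-probability rule).
* **Cross-product selection** (phase 2): per stage, a latent categorical
  indicator selects among an enumerated candidate-model set; its posterior
  frequencies are the model probabilities, and summarizing any coefficient
  over only the draws in which its covariate is included yields the
  model-averaged ("conditional") estimates.

Coefficients excluded under the current model evolve under their prior
(prior-as-pseudoprior, the simplest Carlin-Chib scheme), which preserves
between-model mixing.  Zero-inflated covariates are all-or-nothing term
pairs: the binary (absence) and continuous (magnitude) columns enter or
leave the model together, and interaction terms require both main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CandidateModel",
    "CandidateModelSet",
    "ScreeningSpec",
    "SelectionSummary",
    "final_candidate_sets",
    "apply_inclusion_rule",
    "categorical_draw",
    "sample_model_indicator",
    "screen_covariates",
    "summarize_selection",
]


@dataclass(frozen=True)
class CandidateModel:
    """One occurrence model: a named inclusion pattern over covariate terms.

    ``terms`` are design-matrix term names (a zero-inflated pair is a
    single term); every model implicitly includes the stage intercept.
    Interaction terms (named ``"a:b"``) require both main effects.
    """

    name: str
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":", 1)
                if a not in self.terms or b not in self.terms:
                    raise ValueError(
                        f"model {self.name!r}: interaction {t!r} requires both main effects"
                    )


@dataclass(frozen=True)
class CandidateModelSet:
    """Per-stage candidate model lists for cross-product selection."""

    models_by_stage: Mapping[str, tuple[CandidateModel, ...]]

    def models_for(self, stage: str) -> tuple[CandidateModel, ...]:
        models = self.models_by_stage.get(stage, ())
        if not models:
            raise KeyError(f"no candidate models configured for stage {stage!r}")
        return tuple(models)

    def stages(self) -> list[str]:
        return list(self.models_by_stage)


@dataclass(frozen=True)
class ScreeningSpec:
    """Per-stage candidate terms for global inclusion-indicator screening."""

    terms_by_stage: Mapping[str, tuple[str, ...]]

    def terms_for(self, stage: str) -> tuple[str, ...]:
        return tuple(self.terms_by_stage.get(stage, ()))


# The six final candidate occurrence models: intercept-only; the
# zero-inflated cone-crop pair; whitebark pine landscape area; Douglas-fir
# landscape area; cone pair + whitebark area; whitebark + Douglas-fir area.
_FINAL_MODELS = {
    "M1": CandidateModel("M1", ()),
    "M2": CandidateModel("M2", ("cone_density",)),
    "M3": CandidateModel("M3", ("wbp_landscape_area",)),
    "M4": CandidateModel("M4", ("df_landscape_area",)),
    "M5": CandidateModel("M5", ("cone_density", "wbp_landscape_area")),
    "M6": CandidateModel("M6", ("wbp_landscape_area", "df_landscape_area")),
}

# Stage-specific availability: cone-crop models only when cones exist (late
# summer, fall harvest); Douglas-fir landscape models during breeding and
# post-harvest, when nutcrackers forage on Douglas-fir seeds.
_FINAL_AVAILABILITY = {
    "breeding": ("M1", "M3", "M4", "M6"),
    "early_summer": ("M1", "M3"),
    "late_summer": ("M1", "M2", "M3", "M5"),
    "fall_harvest": ("M1", "M2", "M3", "M5"),
    "post_harvest": ("M1", "M3", "M4", "M6"),
}


def final_candidate_sets(
    stages: Sequence[str] | None = None,
) -> CandidateModelSet:
    """The default per-stage final candidate model sets (M1-M6)."""
    stages = list(stages) if stages is not None else list(_FINAL_AVAILABILITY)
    return CandidateModelSet(
        models_by_stage={
            s: tuple(_FINAL_MODELS[m] for m in _FINAL_AVAILABILITY[s]) for s in stages
        }
    )


def apply_inclusion_rule(inclusion_probability: float, threshold: float = 0.5) -> bool:
    """Median-probability retention rule: keep a covariate only when its
    posterior inclusion probability strictly exceeds the threshold — a
    covariate at exactly 0.5 is excluded."""
    return inclusion_probability > threshold


def categorical_draw(log_weights: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index from unnormalized log weights (underflow-safe)."""
    w = np.asarray(log_weights, dtype=float)
    w = w - w.max()
    p = np.exp(w)
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def sample_model_indicator(
    z: np.ndarray,
    base_lp: np.ndarray,
    term_contributions: np.ndarray,
    model_masks: Sequence[np.ndarray],
    rng: np.random.Generator,
    log_prior: np.ndarray | None = None,
) -> int:
    """Full-conditional draw of the latent model indicator for one stage.

    Parameters
    ----------
    z
        Latent occupancy states for the stage's units (0/1).
    base_lp
        Linear-predictor part shared by all models (intercept + random
        effects), per unit.
    term_contributions
        ``(n_units, K)`` per-column contributions ``beta_k * x_k`` under the
        current coefficient values (pseudoprior values for columns excluded
        from the current model).
    model_masks
        One boolean column mask per candidate model.
    log_prior
        Log prior over models; uniform when omitted.

    The full conditional is ``prior(m) * prod_units Bernoulli(z | psi_m)``;
    the pseudoprior factors cancel because excluded coefficients keep their
    prior distribution under every model.
    """
    zf = np.asarray(z, dtype=float)
    n_models = len(model_masks)
    if log_prior is None:
        log_prior = np.full(n_models, -np.log(n_models))
    lls = np.empty(n_models)
    for m, mask in enumerate(model_masks):
        lp = base_lp + term_contributions[:, mask].sum(axis=1)
        lls[m] = (zf * lp - np.logaddexp(0.0, lp)).sum()
    return categorical_draw(lls + log_prior, rng)


@dataclass
class SelectionSummary:
    """Posterior selection summaries for one fitted radius class.

    ``model_probabilities`` — stage x model table of indicator
    frequencies (rows sum to 1).  ``inclusion_probabilities`` — per
    (stage, term) posterior inclusion probability.  ``conditional_estimates``
    — coefficient summaries over only the draws where the term's model was
    selected, i.e. model-averaged estimates, with the inclusion probability
    in ``support``.
    """

    model_probabilities: pd.DataFrame
    inclusion_probabilities: pd.DataFrame
    conditional_estimates: pd.DataFrame

    def to_yaml_dict(self) -> dict:
        return {
            "model_probabilities": {
                stage: {m: float(v) for m, v in row.items() if not np.isnan(v)}
                for stage, row in self.model_probabilities.iterrows()
            },
            "inclusion_probabilities": [
                dict(r._asdict()) for r in self.inclusion_probabilities.itertuples(index=False)
            ],
            "conditional_estimates": [
                {
                    k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                    for k, v in r._asdict().items()
                }
                for r in self.conditional_estimates.itertuples(index=False)
            ],
        }


def summarize_selection(draws) -> SelectionSummary:
    """Summarize an indicator-mode posterior into model and inclusion
    probabilities plus conditional (model-averaged) coefficient estimates.

    ``draws`` is a :class:`~nutcracker_occupancy.occupancy_mcmc.PosteriorDraws`
    fitted with a :class:`CandidateModelSet`.  Conditional estimates for a
    term never included in any sampled model are reported as unavailable
    (NaN mean/interval, support 0).
    """
    if "model_index" not in draws.params:
        raise ValueError("draws do not contain a model-indicator chain")
    stage_names = draws.meta["stage_names"]
    columns = draws.meta["columns"]
    terms = draws.meta["terms"]
    cand = draws.meta["candidate_models"]
    idx = draws.stacked("model_index")          # (ndraw, S)
    beta = draws.stacked("beta")                # (ndraw, S, K)

    all_model_names = sorted(
        {m["name"] for s in stage_names for m in cand[s]},
        key=lambda name: [m["name"] for s in stage_names for m in cand[s]].index(name),
    )
    prob_table = pd.DataFrame(
        np.nan, index=stage_names, columns=all_model_names, dtype=float
    )
    incl_rows = []
    cond_rows = []
    for s_i, s in enumerate(stage_names):
        models = cand[s]
        counts = np.bincount(idx[:, s_i], minlength=len(models)).astype(float)
        probs = counts / counts.sum()
        for m_i, m in enumerate(models):
            prob_table.loc[s, m["name"]] = probs[m_i]
        stage_terms = sorted({t for m in models for t in m["terms"]})
        for term in stage_terms:
            has_term = np.array([term in m["terms"] for m in models])
            included = has_term[idx[:, s_i]]
            p_incl = float(included.mean())
            incl_rows.append((s, term, p_incl))
            for col in terms[term]:
                k = columns.index(col)
                if included.any():
                    vals = beta[included, s_i, k]
                    lo, hi = np.percentile(vals, [2.5, 97.5])
                    cond_rows.append(
                        (s, term, col, float(vals.mean()), float(lo), float(hi), p_incl)
                    )
                else:
                    cond_rows.append((s, term, col, np.nan, np.nan, np.nan, 0.0))
    return SelectionSummary(
        model_probabilities=prob_table,
        inclusion_probabilities=pd.DataFrame(
            incl_rows, columns=["stage", "term", "inclusion_probability"]
        ),
        conditional_estimates=pd.DataFrame(
            cond_rows,
            columns=["stage", "term", "column", "mean", "lower95", "upper95", "support"],
        ),
    )


def screen_covariates(
    data,
    terms: ScreeningSpec | Sequence[str],
    settings=None,
    priors=None,
    config=None,
    threshold: float = 0.5,
):
    """Phase-1 covariate screening by posterior inclusion probability.

    Fits the global model with independent Bernoulli(0.5) inclusion
    indicators per term and retains the terms with ``P(I_j = 1 | y) >
    threshold`` — note the strict inequality: a term at exactly the
    threshold is excluded.  Returns ``(report, retained)`` where ``report``
    is a (stage, term, inclusion_probability, retained) table and
    ``retained`` maps stage to the surviving term names.  Screening runs
    whose indicator chains disagree strongly between chains are flagged in
    ``report.attrs['converged']``.
    """
    from . import occupancy_mcmc as om

    if settings is None:
        settings = om.MCMCSettings()
    if priors is None:
        priors = om.Priors()
    if config is None:
        config = om.ModelConfig()
    if not isinstance(terms, ScreeningSpec):
        terms = ScreeningSpec({s: tuple(terms) for s in data.stage_names})
    draws = om.run_mcmc(
        data, settings=settings, priors=priors, config=config, selection=terms
    )
    incl = draws.params["incl"]  # (chains, draws, S, Tmax)
    rows = []
    retained: dict[str, list[str]] = {}
    converged = True
    for s_i, s in enumerate(data.stage_names):
        stage_terms = terms.terms_for(s)
        retained[s] = []
        for t_i, term in enumerate(stage_terms):
            per_chain = incl[:, :, s_i, t_i].mean(axis=1)
            p = float(per_chain.mean())
            if per_chain.max() - per_chain.min() > 0.5:
                converged = False
            keep = apply_inclusion_rule(p, threshold)
            rows.append((s, term, p, keep))
            if keep:
                retained[s].append(term)
    report = pd.DataFrame(
        rows, columns=["stage", "term", "inclusion_probability", "retained"]
    )
    report.attrs["converged"] = converged
    return report, retained
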