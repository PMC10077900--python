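"""Presence and abundance mixed models with empirical null distributions.

Two analyses share one modelling path:

* presence: within mutual-nearest-neighbour plot pairs, each transformed
  response (logit evenness / log richness, per growth form) is regressed
  on a 0/1 indicator that the plot holds at least one member of the
  focal set, with pair identity and survey year as random intercepts.
* abundance: restricted to plots holding at least one focal member, the
  response is regressed on the natural log of the summed focal cover,
  with year, park and ecoregion random intercepts.  The focal term's
  contribution is screened by the AIC difference between the full model
  and the model without it (both refit by maximum likelihood, since
  REML criteria are not comparable across fixed-effect structures).

Significance is empirical: the identical path is rerun for each
rank-matched null species set, and the p-value is the proportion of
null coefficients at least as large as the observed one (one-sided, as
the null hypothesis is that an equally-rare set associates with the
response at least as strongly).  Null replicates that fail to fit or
converge are dropped and counted; p uses the converged denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import FitResult, LmmError, fit_lmm_arrays
from .metrics import transform
from .ranks import FocalSet

__all__ = [
    "ModelSpec",
    "RESPONSES",
    "fit_lmm",
    "compute_r2",
    "empirical_p",
    "delta_aic",
    "run_presence_analysis",
    "run_abundance_analysis",
]

RESPONSES = (
    ("evenness", "all"),
    ("richness", "all"),
    ("evenness", "herbaceous"),
    ("richness", "herbaceous"),
    ("evenness", "woody"),
    ("richness", "woody"),
)

_TRANSFORM_OF = {"evenness": "logit", "richness": "log"}


@dataclass(frozen=True)
class ModelSpec:
    """What one mixed model regresses on what, and its grouping factors."""

    response: str          # "evenness" | "richness"
    growth_form: str       # "all" | "herbaceous" | "woody"
    predictor: str         # "presence" | "log_abundance"
    random_terms: tuple[str, ...]

    @property
    def transform(self) -> str:
        return _TRANSFORM_OF[self.response]


def fit_lmm(frame: pd.DataFrame, spec: ModelSpec, min_obs: int = 20, start=None, reml=True) -> FitResult:
    """Fit one model from an assembled frame with columns y, x and the factors."""
    factors = [(t, frame[t].to_numpy()) for t in spec.random_terms]
    X = np.column_stack([np.ones(len(frame)), frame["x"].to_numpy(float)])
    return fit_lmm_arrays(
        frame["y"].to_numpy(float),
        X,
        factors,
        fixed_names=("intercept", spec.predictor),
        reml=reml,
        min_obs=min_obs,
        start=start,
    )


def compute_r2(fit: FitResult, fixed_effect_variance: float | None = None) -> tuple[float, float]:
    """Variance explained by fixed effects alone / by the whole model.

    The Gaussian variance-partition form: with v_f the variance of the
    fixed-effect predictions, v_r the summed random-intercept variances
    and v_e the residual variance,

        marginal    = v_f / (v_f + v_r + v_e)
        conditional = (v_f + v_r) / (v_f + v_r + v_e)
    """
    v_f = fit.fixed_var if fixed_effect_variance is None else float(fixed_effect_variance)
    v_r = float(sum(fit.vc.values()))
    total = v_f + v_r + fit.sigma2
    if total <= 0:
        raise ValueError("total variance is zero; R2 undefined")
    return v_f / total, (v_f + v_r) / total


def empirical_p(null_betas, observed: float, two_sided: bool = False) -> tuple[float, str]:
    """Proportion of null coefficients >= the observed coefficient.

    Returns ``(p, report)``; when no null coefficient reaches the
    observed value the report notes the resolution bound
    ``p < 1/n_converged``.
    """
    nulls = np.asarray([b for b in null_betas if np.isfinite(b)], float)
    if nulls.size == 0:
        raise ValueError("empty null ensemble")
    if two_sided:
        count = int((np.abs(nulls) >= abs(observed)).sum())
    else:
        count = int((nulls >= observed).sum())
    p = count / nulls.size
    report = f"p = {p:.4g} ({count}/{nulls.size} null coefficients >= observed)"
    if count == 0:
        report += f"; p < {1.0 / nulls.size:.4g}"
    return p, report


def delta_aic(full, reduced) -> float:
    """AIC(reduced) - AIC(full); >= 2 is taken as support for the predictor.

    Accepts two :class:`FitResult` objects (fitted on identical
    observations, enforced) or two raw AIC numbers.
    """
    if isinstance(full, FitResult) and isinstance(reduced, FitResult):
        if full.n_obs != reduced.n_obs:
            raise ValueError(
                f"full and reduced models fit different data (n={full.n_obs} vs {reduced.n_obs})"
            )
        return float(reduced.aic - full.aic)
    return float(reduced) - float(full)


def _response_frame(metrics, plots, response, growth_form, epsilon):
    """plot-indexed frame with the transformed response and grouping columns."""
    sub = metrics.loc[metrics["growth_form"] == growth_form, ["plot_id", response]]
    if response == "richness":
        sub = sub.loc[sub["richness"] > 0]
        y = transform(sub["richness"].to_numpy(float), "log")
    else:
        sub = sub.loc[sub["evenness"].notna()]
        y = transform(sub["evenness"].to_numpy(float), "logit", epsilon)
    frame = pd.DataFrame({"plot_id": sub["plot_id"].to_numpy(), "y": y})
    keep = ["plot_id", "year", "park_id", "ecoregion_l4"]
    return frame.merge(plots[keep], on="plot_id", how="left").set_index("plot_id")


def _set_cover_by_plot(cover, species_set) -> pd.Series:
    sub = cover.loc[cover["species_id"].isin(species_set)]
    return sub.groupby("plot_id")["cover"].sum()


def _reduced_aic(frame, spec, min_obs):
    """ML AIC of the model without the focal predictor, on identical rows."""
    factors = [(t, frame[t].to_numpy()) for t in spec.random_terms]
    return fit_lmm_arrays(
        frame["y"].to_numpy(float),
        np.ones((len(frame), 1)),
        factors,
        fixed_names=("intercept",),
        reml=False,
        min_obs=min_obs,
    )


def _run_analysis(build_frame, sets, spec, min_obs, two_sided, analysis_id):
    """Shared observed-vs-null machinery.

    ``build_frame(species_set)`` assembles the model frame for any
    species set; the focal path and every null path run through it
    identically, differing only in the injected set.
    """
    focal_set, null_sets = sets
    frame = build_frame(focal_set.species)
    # the pilot fit supplies the variance-ratio starting point used by the
    # focal refit and every null replicate alike, so the focal and null
    # paths are identical code with only the species set substituted
    pilot = fit_lmm(frame, spec, min_obs=min_obs, reml=True)
    fit = fit_lmm(frame, spec, min_obs=min_obs, start=pilot.theta, reml=True)
    full_ml = fit_lmm(frame, spec, min_obs=min_obs, start=fit.theta, reml=False)
    reduced_ml = _reduced_aic(frame, spec, min_obs)
    daic = delta_aic(full_ml, reduced_ml)
    r2m, r2c = compute_r2(fit)

    null_rows, betas = [], []
    n_failed = 0
    for k, ns in enumerate(null_sets):
        try:
            nf = fit_lmm(build_frame(ns.species), spec, min_obs=min_obs, start=pilot.theta, reml=True)
        except LmmError:
            n_failed += 1
            continue
        if not nf.converged:
            n_failed += 1
            continue
        betas.append(nf.beta1)
        null_rows.append((analysis_id, spec.response, spec.growth_form, k, nf.beta1))
    if betas:
        p, note = empirical_p(betas, fit.beta1, two_sided=two_sided)
    elif null_sets:
        raise ValueError("no null replicate converged; cannot form an empirical p-value")
    else:
        p, note = np.nan, "no null replicates requested"

    row = {
        "analysis_id": analysis_id,
        "response": spec.response,
        "growth_form": spec.growth_form,
        "predictor": spec.predictor,
        "n": fit.n_obs,
        "beta1": fit.beta1,
        "se": float(fit.se[-1]),
        "marginal_r2": r2m,
        "conditional_r2": r2c,
        "aic_full": full_ml.aic,
        "aic_reduced": reduced_ml.aic,
        "delta_aic": daic,
        "empirical_p": p,
        "p_note": note,
        "n_null_converged": len(betas),
        "n_null_failed": n_failed,
    }
    return row, null_rows


def run_abundance_analysis(
    cover: pd.DataFrame,
    metrics: pd.DataFrame,
    plots: pd.DataFrame,
    focal_set: FocalSet,
    null_sets=(),
    responses=RESPONSES,
    epsilon: float = 1e-6,
    min_obs: int = 20,
    two_sided: bool = False,
    analysis_id: str = "abundance",
):
    """Abundance models over plots holding the focal (or null) set.

    For each response x growth form: the REML coefficient of ln summed
    focal cover, its empirical p against the null ensemble, the ML
    AIC screen against the no-predictor model, and the variance
    partition.  Returns ``(results, null_coefficients)`` frames.
    """
    set_covers = {id(focal_set): _set_cover_by_plot(cover, focal_set.species)}
    for ns in null_sets:
        set_covers[id(ns)] = _set_cover_by_plot(cover, ns.species)
    by_species_key = {frozenset(focal_set.species): id(focal_set)}
    for ns in null_sets:
        by_species_key[frozenset(ns.species)] = id(ns)

    rows, null_rows = [], []
    for response, form in responses:
        spec = ModelSpec(response, form, "log_abundance", ("year", "park_id", "ecoregion_l4"))
        base = _response_frame(metrics, plots, response, form, epsilon)

        def build_frame(species_set, _base=base):
            fc = set_covers[by_species_key[frozenset(species_set)]]
            fc = fc[fc > 0]
            frame = _base.join(fc.rename("focal_cover"), how="inner")
            frame["x"] = np.log(frame["focal_cover"].to_numpy(float))
            return frame

        row, nr = _run_analysis(build_frame, (focal_set, tuple(null_sets)), spec, min_obs, two_sided, analysis_id)
        rows.append(row)
        null_rows.extend(nr)
    return _to_frames(rows, null_rows)


def run_presence_analysis(
    pairs: pd.DataFrame,
    cover: pd.DataFrame,
    metrics: pd.DataFrame,
    plots: pd.DataFrame,
    focal_set: FocalSet,
    null_sets=(),
    responses=RESPONSES,
    epsilon: float = 1e-6,
    min_obs: int = 20,
    two_sided: bool = False,
    analysis_id: str = "presence",
):
    """Presence models over mutual-nearest-neighbour plot pairs.

    The predictor is a 0/1 indicator that the plot holds at least one
    member of the focal (or null) set; random intercepts are pair
    identity and survey year.  A focal set occupying every paired plot
    (or none) has no contrast and raises a constant-predictor error.
    """
    if pairs.empty:
        raise ValueError("empty pair set; cannot run presence analysis")
    pair_of_plot = pd.concat(
        [
            pd.Series(pairs.index.astype(str), index=pairs["plot_a"]),
            pd.Series(pairs.index.astype(str), index=pairs["plot_b"]),
        ]
    ).rename("pair_id")

    occupied = {
        id(s): set(cover.loc[cover["species_id"].isin(s.species), "plot_id"])
        for s in (focal_set, *null_sets)
    }
    by_species_key = {frozenset(s.species): id(s) for s in (focal_set, *null_sets)}

    rows, null_rows = [], []
    for response, form in responses:
        spec = ModelSpec(response, form, "presence", ("pair_id", "year"))
        base = _response_frame(metrics, plots, response, form, epsilon)
        base = base.join(pair_of_plot, how="inner")

        def build_frame(species_set, _base=base):
            frame = _base.copy()
            plots_with = occupied[by_species_key[frozenset(species_set)]]
            frame["x"] = frame.index.isin(plots_with).astype(float)
            return frame

        row, nr = _run_analysis(build_frame, (focal_set, tuple(null_sets)), spec, min_obs, two_sided, analysis_id)
        rows.append(row)
        null_rows.extend(nr)
    return _to_frames(rows, null_rows)


def _to_frames(rows, null_rows):
    results = pd.DataFrame(rows)
    null_df = pd.DataFrame(
        null_rows, columns=["analysis_id", "response", "growth_form", "replicate", "beta1"]
    )
    return results, null_df
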