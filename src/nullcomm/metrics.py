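"""Per-plot community metrics: richness, Shannon evenness, summed cover.

Evenness is Pielou's form of the Shannon index, E = H / ln(S), with
H = -sum p_i ln p_i over the relative covers of the S species of one
growth form in one plot.  E lies in [0, 1] and is undefined for S < 2
(a single-species community has no evenness); such plots keep their
richness but propagate a missing evenness, so they drop out of
evenness models only.

Model-scale transforms: richness is log-transformed (natural log) and
evenness logit-transformed, with boundary values clamped into
(epsilon, 1 - epsilon) first since perfectly even plots (E = 1 exactly)
do occur.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "shannon_evenness",
    "richness",
    "total_cover",
    "transform",
    "compute_metrics",
    "GROWTH_FORMS",
]

GROWTH_FORMS = ("all", "herbaceous", "woody")


def shannon_evenness(covers) -> float:
    """Shannon evenness H/ln(S) of a positive cover vector; NaN when S < 2."""
    c = np.asarray(covers, float)
    if c.size and (c <= 0).any():
        raise ValueError("covers must be strictly positive")
    s = c.size
    if s < 2:
        return float("nan")
    p = c / c.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(s))


def richness(covers) -> int:
    """Number of species present (count of the cover vector)."""
    return int(len(covers))


def total_cover(covers) -> float:
    """Summed percentage cover (the paper's plot-level 'abundance')."""
    return float(np.sum(covers)) if len(covers) else 0.0


def transform(value, kind: str, epsilon: float = 1e-6):
    """Model-scale transform: natural log, or logit with boundary clamping."""
    v = np.asarray(value, float)
    if kind == "log":
        if np.any(v <= 0):
            raise ValueError("log transform requires positive values")
        out = np.log(v)
    elif kind == "logit":
        if np.any((v < 0) | (v > 1)):
            raise ValueError("logit transform requires values in [0, 1]")
        vv = np.clip(v, epsilon, 1.0 - epsilon)
        out = np.log(vv / (1.0 - vv))
    else:
        raise ValueError(f"unknown transform {kind!r}; expected 'log' or 'logit'")
    return float(out) if np.isscalar(value) else out


def _form_metrics(cov: pd.DataFrame, plot_ids: pd.Index, form: str) -> pd.DataFrame:
    """Vectorised richness/evenness/total per plot for one cover subset."""
    if cov.empty:
        g = pd.DataFrame(
            {"richness": 0, "total_cover": 0.0, "evenness": np.nan}, index=plot_ids
        )
    else:
        grp = cov.groupby("plot_id", sort=False)["cover"]
        s = grp.size()
        tot = grp.sum()
        p = cov["cover"].to_numpy() / tot.reindex(cov["plot_id"]).to_numpy()
        plogp = pd.Series(-p * np.log(p), index=cov["plot_id"].to_numpy())
        h = plogp.groupby(level=0, sort=False).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            e = h / np.log(s)
        e[s < 2] = np.nan
        g = pd.DataFrame({"richness": s, "total_cover": tot, "evenness": e})
        g = g.reindex(plot_ids)
        g["richness"] = g["richness"].fillna(0).astype(int)
        g["total_cover"] = g["total_cover"].fillna(0.0)
    g.index.name = "plot_id"
    out = g.reset_index()
    out.insert(1, "growth_form", form)
    return out[["plot_id", "growth_form", "richness", "evenness", "total_cover"]]


def compute_metrics(
    cover: pd.DataFrame,
    species: pd.DataFrame,
    plots: pd.DataFrame,
    forms=GROWTH_FORMS,
) -> pd.DataFrame:
    """Tidy metrics table over every retained plot and growth form.

    ``species`` must carry the ``growth_form`` column from
    :func:`nullcomm.ingest.classify_growth_form`; species classified as
    ``excluded`` contribute to no growth form, including "all".  Plots
    with no member of a form get richness 0, total 0 and missing
    evenness.
    """
    if "growth_form" not in species.columns:
        raise ValueError("species table lacks 'growth_form'; run classify_growth_form first")
    form_of = species.set_index("species_id")["growth_form"]
    cov = cover.assign(form=cover["species_id"].map(form_of))
    cov = cov.loc[cov["form"].isin(("herbaceous", "woody")) & (cover["cover"] > 0)]
    plot_ids = pd.Index(plots["plot_id"].unique())
    parts = []
    for form in forms:
        sub = cov if form == "all" else cov.loc[cov["form"] == form]
        parts.append(_form_metrics(sub, plot_ids, form))
    return pd.concat(parts, ignore_index=True)
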