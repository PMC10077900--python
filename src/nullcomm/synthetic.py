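"""Synthetic plot x species communities with a known focal-guild effect.

The generator emulates the statistical structure of a continental
vegetation-plot survey: a heavy-tailed global species-abundance
distribution (most species rare), hierarchical spatial grouping
(ecoregion > park > plot) with group-level intercepts on community
structure, survey-year effects, and a minority focal guild of
herbaceous taxa spanning a wide window of the rank-abundance curve and
occupying a small fraction of plots.

Community mechanism (core-satellite).  Each flora splits at an
occupancy knee into a common core and a satellite pool.  Within a
plot, the core species present receive relative covers from a
dominance-decay (geometric-series) weighting: the core species at
local commonness position k gets weight ``m_i * (1 - delta)^(k-1)``,
where ``m_i`` is a lognormal species size score and ``delta`` the
plot's dominance parameter; core covers are normalised to the plot's
total.  Satellite species (the focal guild's rank window lies entirely
in this pool) occur rarely -- their rank sets their occupancy -- but
their cover when present is an independent lognormal draw, unrelated
to rank or to the plot's dominance; satellite covers add on top of the
core total.  Smaller ``delta`` means a flatter core and a more even
community.  The focal effect is causal on dominance:

    logit(delta_plot) = logit(delta0) + u_eco + u_park + u_year + e
                        - gamma * [ln(1 + focal_cover/h) - ln(1 + c0/h)]

so focal cover increases evenness (gamma > 0) without touching
richness, while the woody stratum is generated independently with no
focal term and acts as a negative control.  Two properties follow by
construction.  Under gamma = 0, focal cover is independent of the
dominance series, so it carries no information about evenness beyond
its own (small) contribution to the metric.  And the focal guild is
exchangeable with rank-matched null sets: both are satellite species
whose covers come from the identical distribution, with guild
occupancy calibrated to the plot fraction a null set is expected to
occupy.

The generator's true evenness coefficient (on the logit-evenness ~
ln focal cover scale actually fitted downstream) has no closed form; it
is obtained by a large-sample regression on data generated with all
group and residual noise switched off (see :func:`true_effect`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate", "true_effect", "make_fixture", "write_csvs"]

_CHUNK = 2048

_HEMI_GENERA = (
    ("Pedicularis", 0.32), ("Castilleja", 0.25), ("Krameria", 0.20),
    ("Comandra", 0.13), ("Aureolaria", 0.02), ("Cordylanthus", 0.02),
    ("Dasistoma", 0.01), ("Euphrasia", 0.01), ("Geocaulon", 0.01),
    ("Orthocarpus", 0.01), ("Triphysaria", 0.01), ("Seymeria", 0.01),
)

_HERB_HABITS = ("Forb/herb", "Graminoid", "Subshrub", "Forb/herb, Subshrub")
_WOODY_HABITS = ("Tree", "Shrub")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Sizes default to a desk-scale mirror of a continental survey:
    20 ecoregions x 2 parks x 50 plots and a 2,000-species pool with a
    78-taxon focal guild occupying ~13% of plots across a wide
    window of the rank-abundance curve.
    """

    n_species: int = 2000
    n_focal: int = 78
    n_ecoregions: int = 20
    parks_per_ecoregion: int = 2
    plots_per_park: int = 50
    # lognormal species size scores (relative within-plot weighting)
    sad_mean: float = 0.0
    sad_sigma: float = 0.7
    # occupancy: two-regime power law.  A "common flora" block
    # (ranks <= occupancy_knee * n_species) with a shallow decay carries
    # most of plot richness; beyond the knee the decay is steeper and its
    # level is anchored so that a rank-window species set of guild size is
    # expected to occupy focal_occupancy_target of plots.
    occupancy_decay: float = 0.5          # satellite (window) regime
    occupancy_decay_common: float = 0.45  # common-flora regime
    occupancy_knee: float = 0.10          # knee as a fraction of n_species
    occupancy_max: float = 0.6
    # satellite species cover-given-presence (percent), iid lognormal
    satellite_cover_mean: float = 0.10
    satellite_cover_sigma: float = 0.8
    # dominance-decay parameters
    dominance_base: float = 0.20          # delta0, herbaceous
    dominance_base_woody: float = 0.30
    effect_evenness: float = 0.0          # gamma, per unit ln(1 + F/effect_halfcover)
    effect_halfcover: float = 0.1         # percent cover at which the effect term ~ ln 2
    effect_center_cover: float = 0.10     # percent; effect term centred at this focal cover
    effect_richness: float = 0.0          # extra species per unit ln(1 + focal cover)
    # random-intercept standard deviations on the logit-dominance scale
    sd_ecoregion: float = 0.30
    sd_park: float = 0.20
    sd_year: float = 0.10
    sd_resid: float = 0.20
    sd_park_occupancy: float = 0.15       # lognormal sd of park occupancy multiplier
    focal_occupancy_target: float = 0.13
    # focal guild placement in the rank-abundance curve (rank fractions)
    focal_rank_lo: float = 0.10
    focal_rank_hi: float = 0.97
    # 0 = uniform placement across the window (keeps the guild statistically
    # exchangeable with uniformly drawn null sets); > 0 concentrates guild
    # ranks toward the common end, reproducing the rank-clustering bias the
    # method is known to carry
    focal_rank_concentration: float = 0.0
    woody_fraction: float = 0.075
    unlisted_fraction: float = 0.01
    year_span: tuple[int, int] = (1997, 2012)
    total_cover_mean: float = 70.0        # percent, herbaceous stratum
    total_cover_sigma: float = 0.30
    total_cover_mean_woody: float = 50.0
    area_m2: float = 400.0
    stratum_split_frac: float = 0.04      # herb rows split across two strata
    seed: int = 0

    @property
    def n_plots(self) -> int:
        return self.n_ecoregions * self.parks_per_ecoregion * self.plots_per_park


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated dataset."""

    per_plot: pd.DataFrame  # plot_id, delta, focal_cover, u_eco, u_park, u_year, resid
    beta1: float | None     # logit-evenness slope on ln focal cover; None if not computed
    config: GeneratorConfig


def _occupancy_prob(ranks: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Two-regime rank-occupancy curve (see GeneratorConfig)."""
    if not 0.0 < cfg.focal_occupancy_target < 1.0:
        raise ValueError("infeasible config: focal_occupancy_target must be in (0, 1)")
    knee = max(2.0, cfg.occupancy_knee * cfg.n_species)
    lo = cfg.focal_rank_lo * cfg.n_species
    hi = cfg.focal_rank_hi * cfg.n_species
    window = np.arange(int(lo), int(hi) + 1, dtype=float)
    mean_window = np.mean(window ** -cfg.occupancy_decay)
    c_mult = np.exp(cfg.sd_park_occupancy**2 / 2.0)
    q_target = -np.log1p(-cfg.focal_occupancy_target) / cfg.n_focal / c_mult
    c2 = q_target / mean_window
    q = np.where(
        ranks <= knee,
        cfg.occupancy_max * ranks ** -cfg.occupancy_decay_common,
        c2 * ranks ** -cfg.occupancy_decay,
    )
    return np.minimum(cfg.occupancy_max, q)


def _focal_boost(q_focal: np.ndarray, cfg: GeneratorConfig) -> float:
    """Occupancy multiplier putting the guild at the target plot fraction."""
    target = cfg.focal_occupancy_target
    if not 0.0 < target < 1.0:
        raise ValueError("focal_occupancy_target must be in (0, 1)")
    c = np.exp(cfg.sd_park_occupancy**2 / 2.0)  # mean park multiplier

    def miss(loglam):
        p = np.minimum(0.95, c * q_focal * np.exp(loglam))
        return np.log1p(-p).sum() - np.log1p(-target)

    if miss(20.0) > 0:
        raise ValueError(
            f"infeasible config: focal_occupancy_target={target} unreachable "
            f"with {len(q_focal)} focal taxa"
        )
    return float(np.exp(brentq(miss, -20.0, 20.0, xtol=1e-10)))


def _species_table(cfg: GeneratorConfig, rng: np.random.Generator):
    """Species catalog ordered by intended global rank (1 = most common)."""
    s = cfg.n_species
    m = np.sort(rng.lognormal(cfg.sad_mean, cfg.sad_sigma, s))[::-1]
    ids = np.array([f"S{i + 1:05d}" for i in range(s)])
    # Woody and habit-unlisted species live outside the focal rank window:
    # in the common-flora block (widespread canopy dominants) or the very
    # rare tail.  The window itself is entirely herbaceous, so null sets
    # drawn from it match the guild in growth-form composition.
    lo = int(round(cfg.focal_rank_lo * s))
    hi = int(round(cfg.focal_rank_hi * s)) - 1
    knee = int(round(cfg.occupancy_knee * s))
    zone = np.concatenate([np.arange(0, min(knee, lo)), np.arange(hi + 1, s)])
    n_woody = int(round(cfg.woody_fraction * s))
    n_unlisted = int(round(cfg.unlisted_fraction * s))
    if n_woody + n_unlisted > len(zone):
        raise ValueError(
            f"infeasible config: {n_woody + n_unlisted} woody/unlisted species do not "
            f"fit outside the focal rank window ({len(zone)} ranks available)"
        )
    is_woody = np.zeros(s, bool)
    is_unlisted = np.zeros(s, bool)
    special = rng.choice(zone, size=n_woody + n_unlisted, replace=False)
    is_woody[special[:n_woody]] = True
    is_unlisted[special[n_woody:]] = True
    is_herb = ~(is_woody | is_unlisted)

    cand = np.flatnonzero(is_herb[: hi + 1])
    cand = cand[cand >= lo]
    if len(cand) < cfg.n_focal:
        raise ValueError(
            f"infeasible config: only {len(cand)} herbaceous species in the "
            f"focal rank window, {cfg.n_focal} required"
        )
    w = np.exp(-cfg.focal_rank_concentration * (cand - lo) / max(hi - lo, 1))
    is_focal = np.zeros(s, bool)
    is_focal[rng.choice(cand, size=cfg.n_focal, replace=False, p=w / w.sum())] = True

    habit = np.empty(s, object)
    habit[is_herb] = rng.choice(_HERB_HABITS, is_herb.sum(), p=(0.55, 0.3, 0.1, 0.05))
    habit[is_woody] = rng.choice(_WOODY_HABITS, is_woody.sum(), p=(0.45, 0.55))
    habit[is_unlisted] = rng.choice(("Vine", "Lichenous", ""), is_unlisted.sum())

    genera, gw = zip(*_HEMI_GENERA)
    genus = np.array([f"Genus{i // 8:04d}" for i in range(s)], object)
    genus[is_focal] = rng.choice(genera, cfg.n_focal, p=np.array(gw) / sum(gw))
    life = rng.choice(("perennial", "annual", "unknown"), s, p=(0.7, 0.2, 0.1))
    life[is_focal] = rng.choice(("perennial", "annual"), cfg.n_focal, p=(0.9, 0.1))

    species = pd.DataFrame(
        {
            "species_id": ids,
            "genus": genus,
            "growth_habit": habit,
            "is_hemiparasite": is_focal,
            "life_history": life,
        }
    )
    return species, m, is_herb | is_focal, is_woody & ~is_focal, is_focal


def _plots_table(cfg: GeneratorConfig, rng: np.random.Generator):
    n_eco, n_park = cfg.n_ecoregions, cfg.n_ecoregions * cfg.parks_per_ecoregion
    n = cfg.n_plots
    eco_of_park = np.repeat(np.arange(n_eco), cfg.parks_per_ecoregion)
    park_of_plot = np.repeat(np.arange(n_park), cfg.plots_per_park)
    eco_of_plot = eco_of_park[park_of_plot]
    ncol = int(np.ceil(np.sqrt(n_eco)))
    eco_lon = -120.0 + 4.0 * (np.arange(n_eco) % ncol)
    eco_lat = 31.0 + 4.0 * (np.arange(n_eco) // ncol)
    park_lon = eco_lon[eco_of_park] + rng.normal(0, 0.5, n_park)
    park_lat = eco_lat[eco_of_park] + rng.normal(0, 0.5, n_park)
    lon = park_lon[park_of_plot] + rng.normal(0, 0.05, n)
    lat = park_lat[park_of_plot] + rng.normal(0, 0.05, n)
    years = rng.integers(cfg.year_span[0], cfg.year_span[1] + 1, n)
    plots = pd.DataFrame(
        {
            "plot_id": [f"P{i + 1:06d}" for i in range(n)],
            "latitude": np.clip(lat, -89.9, 89.9),
            "longitude": np.clip(lon, -179.9, 179.9),
            "area_m2": cfg.area_m2,
            "year": years,
            "park_id": [f"PK{p + 1:03d}" for p in park_of_plot],
            "ecoregion_l4": [f"E{e + 1:03d}" for e in eco_of_plot],
        }
    )
    return plots, eco_of_plot, park_of_plot, years


class _Occupants:
    """Occupied (plot, species) cells of one chunk, in rank order per plot."""

    def __init__(self, occ: np.ndarray):
        self.n_rows = occ.shape[0]
        self.pi, self.si = np.nonzero(occ)
        # local commonness position: 1, 2, ... within each plot's occupant list
        starts = np.searchsorted(self.pi, np.arange(self.n_rows))
        self.pos = np.arange(len(self.pi)) - starts[self.pi]

    def covers(self, delta, m_sub, totals):
        """Dominance-decay covers at the occupied cells."""
        w = np.exp(self.pos * np.log1p(-delta)[self.pi]) * m_sub[self.si]
        norm = np.bincount(self.pi, weights=w, minlength=self.n_rows)
        norm[norm == 0.0] = 1.0
        return w / norm[self.pi] * totals[self.pi]

    def sum_over(self, mask_cols, values):
        """Per-plot sum of ``values`` over cells whose species is in ``mask_cols``."""
        sel = mask_cols[self.si]
        return np.bincount(self.pi[sel], weights=values[sel], minlength=self.n_rows)


def generate(cfg: GeneratorConfig, compute_truth: bool = True):
    """Generate ``(cover, species, plots, truth)`` under the config.

    Output tables use exactly the CSV dialects consumed by
    :mod:`nullcomm.ingest`.  Byte-identical for a fixed config (the seed
    is part of the config).
    """
    rng = np.random.default_rng(cfg.seed)
    species, m, herb_mask, woody_mask, focal_mask = _species_table(cfg, rng)
    plots, eco, park, years = _plots_table(cfg, rng)
    n = cfg.n_plots

    u_eco = rng.normal(0, cfg.sd_ecoregion, cfg.n_ecoregions)
    u_park = rng.normal(0, cfg.sd_park, cfg.n_ecoregions * cfg.parks_per_ecoregion)
    year_levels = np.arange(cfg.year_span[0], cfg.year_span[1] + 1)
    u_year = rng.normal(0, cfg.sd_year, len(year_levels))
    u_year_of_plot = u_year[years - cfg.year_span[0]]
    resid = rng.normal(0, cfg.sd_resid, n)
    eta_base = logit(cfg.dominance_base) + u_eco[eco] + u_park[park] + u_year_of_plot + resid

    # independent woody dominance: own group effects, no focal term
    uw_eco = rng.normal(0, cfg.sd_ecoregion, cfg.n_ecoregions)
    uw_park = rng.normal(0, cfg.sd_park, cfg.n_ecoregions * cfg.parks_per_ecoregion)
    uw_year = rng.normal(0, cfg.sd_year, len(year_levels))
    delta_woody = expit(
        logit(cfg.dominance_base_woody)
        + uw_eco[eco] + uw_park[park] + uw_year[years - cfg.year_span[0]]
        + rng.normal(0, cfg.sd_resid, n)
    )

    # independent park suitability multipliers per stratum and per pool
    # (core vs satellite), so that focal cover is uncoupled from core
    # richness and from the woody stratum even at park level; the
    # satellite multiplier is shared by the guild and every null set
    def _mult():
        return np.exp(rng.normal(0, cfg.sd_park_occupancy, len(u_park)))[park]

    park_mult_hc, park_mult_hs = _mult(), _mult()
    park_mult_wc, park_mult_ws = _mult(), _mult()
    totals_h = rng.lognormal(np.log(cfg.total_cover_mean), cfg.total_cover_sigma, n)
    totals_w = rng.lognormal(np.log(cfg.total_cover_mean_woody), cfg.total_cover_sigma, n)

    ranks_all = np.arange(1, cfg.n_species + 1)
    knee_rank = round(cfg.occupancy_knee * cfg.n_species)
    lo_rank = round(cfg.focal_rank_lo * cfg.n_species)
    if knee_rank > lo_rank:
        raise ValueError("occupancy_knee must not exceed focal_rank_lo")
    core_mask = ranks_all <= knee_rank

    def split(form_mask):
        core = np.flatnonzero(form_mask & core_mask)
        sat = np.flatnonzero(form_mask & ~core_mask)
        qc = _occupancy_prob(ranks_all[core].astype(float), cfg)
        qs = _occupancy_prob(ranks_all[sat].astype(float), cfg)
        return core, sat, qc, qs

    hc_idx, hs_idx, q_hc, q_hs = split(herb_mask)
    wc_idx, ws_idx, q_wc, q_ws = split(woody_mask)
    focal_in_sat = focal_mask[hs_idx]
    lam = _focal_boost(q_hs[focal_in_sat], cfg)
    m_hc, m_wc = m[hc_idx], m[wc_idx]
    sat_mu = np.log(cfg.satellite_cover_mean)

    rows_plot, rows_sp, rows_cov, rows_form = [], [], [], []
    delta_final = np.empty(n)
    focal_cover = np.zeros(n)
    for start in range(0, n, _CHUNK):
        sl = slice(start, min(start + _CHUNK, n))
        c = sl.stop - sl.start
        # herbaceous satellites first: the focal cover they carry sets dominance
        p_hs = np.minimum(0.95, q_hs[None, :] * park_mult_hs[sl, None])
        p_hs[:, focal_in_sat] = np.minimum(0.95, p_hs[:, focal_in_sat] * lam)
        occ_hs = rng.random((c, len(hs_idx))) < p_hs
        os_h = _Occupants(occ_hs)
        cov_hs = rng.lognormal(sat_mu, cfg.satellite_cover_sigma, len(os_h.pi))
        fcov = os_h.sum_over(focal_in_sat, cov_hs)
        if cfg.effect_richness > 0.0:
            extra = rng.poisson(cfg.effect_richness * np.log1p(fcov / cfg.effect_halfcover))
            for i in np.flatnonzero(extra):
                absent = np.flatnonzero(~occ_hs[i])
                k = min(int(extra[i]), len(absent))
                if k:
                    occ_hs[i, rng.choice(absent, k, replace=False)] = True
            os_h = _Occupants(occ_hs)
            cov_hs = rng.lognormal(sat_mu, cfg.satellite_cover_sigma, len(os_h.pi))
            fcov = os_h.sum_over(focal_in_sat, cov_hs)
        t_eff = np.log1p(fcov / cfg.effect_halfcover) - np.log1p(
            cfg.effect_center_cover / cfg.effect_halfcover
        )
        dfin = expit(eta_base[sl] - cfg.effect_evenness * t_eff)
        delta_final[sl] = dfin
        focal_cover[sl] = fcov

        occ_hc = rng.random((c, len(hc_idx))) < np.minimum(
            0.95, q_hc[None, :] * park_mult_hc[sl, None]
        )
        oc_h = _Occupants(occ_hc)
        cov_hc = oc_h.covers(dfin, m_hc, totals_h[sl])

        occ_wc = rng.random((c, len(wc_idx))) < np.minimum(
            0.95, q_wc[None, :] * park_mult_wc[sl, None]
        )
        oc_w = _Occupants(occ_wc)
        cov_wc = oc_w.covers(delta_woody[sl], m_wc, totals_w[sl])
        occ_ws = rng.random((c, len(ws_idx))) < np.minimum(
            0.95, q_ws[None, :] * park_mult_ws[sl, None]
        )
        os_w = _Occupants(occ_ws)
        cov_ws = rng.lognormal(sat_mu, cfg.satellite_cover_sigma, len(os_w.pi))

        for occu, covs, idx_map, form in (
            (oc_h, cov_hc, hc_idx, "field"),
            (os_h, cov_hs, hs_idx, "field"),
            (oc_w, cov_wc, wc_idx, "canopy"),
            (os_w, cov_ws, ws_idx, "canopy"),
        ):
            covs = np.round(covs, 6)  # survey covers are recorded to 1e-6 %
            keep = covs > 0
            rows_plot.append(occu.pi[keep] + sl.start)
            rows_sp.append(idx_map[occu.si[keep]])
            rows_cov.append(covs[keep])
            rows_form.append(np.full(int(keep.sum()), form, dtype=object))

    plot_i = np.concatenate(rows_plot)
    sp_i = np.concatenate(rows_sp)
    covv = np.concatenate(rows_cov)
    strat = np.concatenate(rows_form)

    # split a fraction of herbaceous rows across two strata (ingest sums them back)
    if cfg.stratum_split_frac > 0:
        herb_rows = np.flatnonzero(strat == "field")
        n_split = int(len(herb_rows) * cfg.stratum_split_frac)
        if n_split:
            pick = rng.choice(herb_rows, n_split, replace=False)
            frac = rng.uniform(0.2, 0.8, n_split)
            extra_cov = covv[pick] * (1.0 - frac)
            covv = np.concatenate([covv, extra_cov])
            covv[pick] *= frac
            plot_i = np.concatenate([plot_i, plot_i[pick]])
            sp_i = np.concatenate([sp_i, sp_i[pick]])
            strat = np.concatenate([strat, np.full(n_split, "ground", dtype=object)])

    plot_ids = plots["plot_id"].to_numpy()
    sp_ids = species["species_id"].to_numpy()
    cover = pd.DataFrame(
        {
            "plot_id": plot_ids[plot_i],
            "species_id": sp_ids[sp_i],
            "stratum": strat,
            "cover": covv,
        }
    )
    cover = cover.sort_values(["plot_id", "species_id", "stratum"], kind="mergesort").reset_index(
        drop=True
    )

    per_plot = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "delta": delta_final,
            "focal_cover": focal_cover,
            "u_eco": u_eco[eco],
            "u_park": u_park[park],
            "u_year": u_year_of_plot,
            "resid": resid,
        }
    )
    beta1 = true_effect(cfg) if compute_truth else None
    return cover, species, plots, SyntheticTruth(per_plot, beta1, cfg)


def true_effect(cfg: GeneratorConfig, n_plots_target: int = 12000, _cache={}) -> float:
    """Generator-truth evenness coefficient for a config.

    Defined as the large-sample slope of logit herbaceous evenness on
    ln focal cover across focal plots, with every group intercept and
    the residual dominance noise switched off.  Independent of the
    config's seed; cached per parameter set.

    The slope reflects the generator's full data-generating process:
    the causal dominance pathway plus the guild's own (small)
    mechanical contribution to the evenness metric, so it is slightly
    positive even when the evenness effect is off.
    """
    key = dataclasses.replace(cfg, seed=0)
    if key in _cache:
        return _cache[key]
    scale = max(1, int(np.ceil(n_plots_target / cfg.n_plots)))
    quiet = dataclasses.replace(
        cfg,
        sd_ecoregion=0.0, sd_park=0.0, sd_year=0.0, sd_resid=0.0,
        sd_park_occupancy=0.0,
        plots_per_park=cfg.plots_per_park * scale,
        stratum_split_frac=0.0,
        seed=1_234_567,
    )
    cover, species, plots, truth = generate(quiet, compute_truth=False)
    herb = set(species.loc[species["growth_habit"].isin(
        [h for h in species["growth_habit"].unique()
         if str(h).split(",")[0].strip().lower() in ("forb/herb", "graminoid", "subshrub")]
    ), "species_id"]) | set(species.loc[species["is_hemiparasite"], "species_id"])
    sub = cover[cover["species_id"].isin(herb)]
    grp = sub.groupby("plot_id")["cover"]
    s = grp.size()
    tot = grp.sum()
    p = sub["cover"].to_numpy() / tot.reindex(sub["plot_id"]).to_numpy()
    h = pd.Series(-p * np.log(p), index=sub["plot_id"].to_numpy()).groupby(level=0).sum()
    e = (h / np.log(s)).clip(1e-6, 1 - 1e-6)
    frame = truth.per_plot.set_index("plot_id").join(e.rename("evenness"))
    frame = frame[(frame["focal_cover"] > 0) & (frame["evenness"].notna()) & (s.reindex(frame.index) >= 2)]
    x = np.log(frame["focal_cover"].to_numpy())
    y = logit(frame["evenness"].to_numpy())
    beta = float(np.polyfit(x, y, 1)[0])
    _cache[key] = beta
    return beta


# gamma giving a generator-truth evenness coefficient of about +0.19 on the
# logit-evenness scale at the default study conditions (see docs/methods.md)
EFFECT_GAMMA = 0.8

_FIXTURES = ("tiny_null", "tiny_effect", "pairing_grid", "single_taxon_plots")


def _tiny_config(**over) -> GeneratorConfig:
    base = dict(
        n_species=300, n_focal=20, n_ecoregions=4, parks_per_ecoregion=2,
        plots_per_park=25, focal_occupancy_target=0.15, seed=11,
    )
    base.update(over)
    return GeneratorConfig(**base)


def make_fixture(name: str):
    """Small deterministic bundled datasets for tests.

    Returns ``(cover, species, plots, truth_or_None)``.
    """
    if name == "tiny_null":
        return generate(_tiny_config(), compute_truth=False)
    if name == "tiny_effect":
        return generate(_tiny_config(effect_evenness=EFFECT_GAMMA, seed=13), compute_truth=False)
    if name == "pairing_grid":
        # one ecoregion with a non-mutual NN chain (0, 1, 3 degrees apart),
        # a duplicate-coordinate pair, and a singleton ecoregion
        plots = pd.DataFrame(
            {
                "plot_id": ["G01", "G02", "G03", "G04", "G05", "G06"],
                "latitude": [40.0, 40.0, 40.0, 42.0, 42.0, 45.0],
                "longitude": [-100.0, -99.0, -96.0, -90.0, -90.0, -80.0],
                "area_m2": 400.0,
                "year": 2005,
                "park_id": ["PK1", "PK1", "PK1", "PK2", "PK2", "PK3"],
                "ecoregion_l4": ["EA", "EA", "EA", "EB", "EB", "EC"],
            }
        )
        species = pd.DataFrame(
            {
                "species_id": ["SPA", "SPB"],
                "genus": ["GenusA", "Castilleja"],
                "growth_habit": ["Forb/herb", "Forb/herb"],
                "is_hemiparasite": [False, True],
                "life_history": ["perennial", "perennial"],
            }
        )
        cover = pd.DataFrame(
            {
                "plot_id": plots["plot_id"],
                "species_id": ["SPA", "SPB"] * 3,
                "stratum": "field",
                "cover": [10.0, 5.0, 8.0, 2.0, 7.0, 1.0],
            }
        )
        return cover, species, plots, None
    if name == "single_taxon_plots":
        cover, species, plots, truth = generate(_tiny_config(seed=17), compute_truth=False)
        # force the first three plots down to a single herbaceous taxon
        herb = species.loc[
            ~species["is_hemiparasite"]
            & species["growth_habit"].str.split(",").str[0].str.strip().str.lower().isin(
                ["forb/herb", "graminoid", "subshrub"]
            ),
            "species_id",
        ].iloc[0]
        victims = plots["plot_id"].iloc[:3]
        keep = ~(cover["plot_id"].isin(set(victims)))
        forced = pd.DataFrame(
            {"plot_id": victims, "species_id": herb, "stratum": "field", "cover": 12.0}
        )
        cover = pd.concat([cover[keep], forced], ignore_index=True)
        return cover, species, plots, truth
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}")


def write_csvs(outdir, cover, species, plots, truth=None) -> None:
    """Write the three input CSVs (and truth.json) for a generated dataset."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cover.to_csv(out / "cover.csv", index=False)
    species.to_csv(out / "species.csv", index=False)
    plots.to_csv(out / "plots.csv", index=False)
    if truth is not None:
        truth.per_plot.to_csv(out / "truth_per_plot.csv", index=False)
        import json

        with open(out / "truth.json", "w") as fh:
            json.dump(
                {"beta1": truth.beta1, "config": dataclasses.asdict(truth.config)},
                fh,
                indent=2,
                default=list,
            )
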