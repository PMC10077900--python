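"""End-to-end runs from a single YAML config.

Stages: ingest -> metrics -> rank abundance -> pairing (presence
analyses only) -> null-set sampling -> inference -> reports.  Every
stage writes a self-describing CSV into the output directory, and all
randomness flows from one master seed recorded in the run log, so a
rerun with the same config reproduces every artifact.

Config layout (YAML)::

    seed: 42
    output_dir: out
    area_keep: 400
    epsilon: 1.0e-6
    inputs: {cover: cover.csv, species: species.csv, plots: plots.csv}
    # or, instead of inputs:
    synthetic: {effect_evenness: 0.5, n_ecoregions: 20, ...}
    analyses:
      - {name: presence_hemi, kind: presence, focal: {guild: true}, n_replicates: 1000}
      - {name: abundance_hemi, kind: abundance, focal: {guild: true}, n_replicates: 1000}
      - {name: abundance_castilleja, kind: abundance, focal: {genus: Castilleja}, n_replicates: 1000}

A focal definition is exactly one of ``guild: true`` (the whole
hemiparasite guild), ``top_k: K`` (its K most abundant taxa),
``rank_band: [lo, hi]`` (its lo-th..hi-th most abundant taxa) or
``genus: Name``.  The null rank window is recomputed from the filtered
focal set, mirroring subset reruns of the same null analysis.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ingest import classify_growth_form, filter_plots, load_tables
from .inference import run_abundance_analysis, run_presence_analysis
from .metrics import compute_metrics
from .pairing import pair_plots
from .ranks import (
    FocalSet,
    build_rank_abundance,
    focal_rank_range,
    occupancy_diagnostics,
    sample_null_sets,
)
from .synthetic import GeneratorConfig, generate, write_csvs

__all__ = ["run", "resolve_focal_set", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the context."""


def resolve_focal_set(species: pd.DataFrame, rank_abundance: pd.DataFrame, focal_def: dict) -> FocalSet:
    """Turn a config focal definition into a concrete species set."""
    keys = {k for k in ("guild", "top_k", "rank_band", "genus") if k in focal_def}
    if len(keys) != 1:
        raise PipelineError(
            f"focal definition must contain exactly one of guild/top_k/rank_band/genus, got {sorted(keys)}"
        )
    guild = species.loc[species["is_hemiparasite"], "species_id"]
    ranked = rank_abundance.loc[rank_abundance["species_id"].isin(set(guild))]
    ranked = ranked.sort_values("rank")  # guild members by global abundance order
    (key,) = keys
    if key == "guild":
        sel, label = ranked["species_id"], "hemiparasites"
    elif key == "top_k":
        k = int(focal_def["top_k"])
        sel, label = ranked["species_id"].head(k), f"top_{k}"
    elif key == "rank_band":
        lo, hi = (int(v) for v in focal_def["rank_band"])
        sel, label = ranked["species_id"].iloc[lo - 1 : hi], f"ranks_{lo}_{hi}"
    else:
        genus_of = species.set_index("species_id")["genus"]
        sel = ranked.loc[ranked["species_id"].map(genus_of) == focal_def["genus"], "species_id"]
        label = f"genus_{focal_def['genus']}"
    members = frozenset(sel)
    if not members:
        raise PipelineError(f"focal definition {focal_def} selects no species")
    return FocalSet(members, label, focal_rank_range(rank_abundance, members))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run(config_path) -> Path:
    """Execute a full pipeline run; returns the artifact directory."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("output_dir", "nullcomm_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    epsilon = float(cfg.get("epsilon", 1e-6))
    area_keep = float(cfg.get("area_keep", 400))
    log: dict = {"seed": seed, "version": __version__, "python": platform.python_version()}

    if "synthetic" in cfg:
        gen_params = dict(cfg["synthetic"] or {})
        gen_params.setdefault("seed", seed)
        gcfg = GeneratorConfig(**gen_params)
        cover_raw, species_raw, plots_raw, truth = generate(gcfg, compute_truth=False)
        write_csvs(outdir / "inputs", cover_raw, species_raw, plots_raw, truth)
        paths = {k: outdir / "inputs" / f"{k}.csv" for k in ("cover", "species", "plots")}
        log["synthetic"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in gen_params.items()}
    elif "inputs" in cfg:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
    else:
        raise PipelineError("config needs either 'inputs' or 'synthetic'")

    cover, species, plots, report = _stage("ingest")(load_tables)(
        paths["cover"], paths["species"], paths["plots"]
    )
    species = classify_growth_form(species, report)
    plots, cover = _stage("filter")(filter_plots)(plots, cover, area_keep, report)
    report.to_json(outdir / "validation_report.json")
    plots.to_csv(outdir / "plots_filtered.csv", index=False)
    cover.to_csv(outdir / "cover_filtered.csv", index=False)
    log["counts"] = {
        "plots_retained": len(plots),
        "species_observed": cover["species_id"].nunique(),
        "cover_rows": len(cover),
    }

    metrics = _stage("metrics")(compute_metrics)(cover, species, plots)
    metrics.to_csv(outdir / "metrics.csv", index=False)

    ra = _stage("rank_abundance")(build_rank_abundance)(cover)
    ra.to_csv(outdir / "rank_abundance.csv", index=False)

    analyses = cfg.get("analyses", [])
    pairs = None
    if any(a.get("kind") == "presence" for a in analyses):
        pairs, discards = _stage("pairing")(pair_plots)(plots)
        pairs.to_csv(outdir / "pairs.csv", index=False)
        discards.to_csv(outdir / "discards.csv", index=False)
        log["counts"]["pairs"] = len(pairs)
        log["counts"]["discards"] = discards["reason"].value_counts().to_dict()

    results, null_coefs, null_set_log = [], [], {}
    for a_idx, a in enumerate(analyses):
        name = a.get("name", f"analysis_{a_idx}")
        focal = _stage(f"focal:{name}")(resolve_focal_set)(species, ra, a.get("focal", {"guild": True}))
        n_rep = int(a.get("n_replicates", 1000))
        sub_seed = int(np.random.SeedSequence([seed, a_idx]).generate_state(1)[0] % (2**31))
        nulls = _stage(f"null_sets:{name}")(sample_null_sets)(ra, focal.species, n_rep, sub_seed)
        with open(outdir / f"null_sets_{name}.json", "w") as fh:
            json.dump(
                {ns.label: sorted(ns.species) for ns in nulls},
                fh,
                separators=(",", ":"),
            )
        null_set_log[name] = {
            "label": focal.label,
            "n_focal": len(focal.species),
            "rank_range": list(focal.rank_range),
            "n_replicates": n_rep,
            "seed": sub_seed,
            "occupancy": occupancy_diagnostics(cover, focal.species),
        }
        kwargs = dict(
            cover=cover, metrics=metrics, plots=plots, focal_set=focal,
            null_sets=nulls, epsilon=epsilon, analysis_id=name,
        )
        if a.get("kind") == "presence":
            res, nc = _stage(f"presence:{name}")(run_presence_analysis)(pairs, **kwargs)
        elif a.get("kind") == "abundance":
            res, nc = _stage(f"abundance:{name}")(run_abundance_analysis)(**kwargs)
        else:
            raise PipelineError(f"analysis {name!r}: unknown kind {a.get('kind')!r}")
        results.append(res)
        null_coefs.append(nc)

    if results:
        pd.concat(results, ignore_index=True).to_csv(outdir / "results.csv", index=False)
        pd.concat(null_coefs, ignore_index=True).to_csv(outdir / "null_coefficients.csv", index=False)
    log["analyses"] = null_set_log
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return outdir
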