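import warnings

import numpy as np
import pandas as pd
import pytest

from nullcomm.ingest import classify_growth_form, filter_plots
from nullcomm.metrics import compute_metrics
from nullcomm.ranks import FocalSet, build_rank_abundance, focal_rank_range
from nullcomm.synthetic import GeneratorConfig, generate, make_fixture

warnings.filterwarnings("ignore", message="grouping factor")


@pytest.fixture(scope="session")
def tiny_null():
    """Small zero-effect dataset (cover, species, plots, truth)."""
    return make_fixture("tiny_null")


@pytest.fixture(scope="session")
def tiny_effect():
    return make_fixture("tiny_effect")


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition dataset, filtered and classified, with metrics."""
    cover, species, plots, truth = generate(GeneratorConfig(seed=7), compute_truth=False)
    species = classify_growth_form(species)
    plots, cover = filter_plots(plots, cover)
    metrics = compute_metrics(cover, species, plots)
    ra = build_rank_abundance(cover)
    observed = set(ra["species_id"])
    focal_ids = frozenset(
        s for s in species.loc[species["is_hemiparasite"], "species_id"] if s in observed
    )
    focal = FocalSet(focal_ids, "hemiparasites", focal_rank_range(ra, focal_ids))
    return {
        "cover": cover,
        "species": species,
        "plots": plots,
        "truth": truth,
        "metrics": metrics,
        "ra": ra,
        "focal": focal,
    }


@pytest.fixture()
def toy_tables(tmp_path):
    """Three tiny, hand-written CSVs with one of everything."""
    cover = tmp_path / "cover.csv"
    species = tmp_path / "species.csv"
    plots = tmp_path / "plots.csv"
    cover.write_text(
        "plot_id,species_id,stratum,cover\n"
        "P1,SA,field,10\n"
        "P1,SB,field,5\n"
        "P2,SA,field,8\n"
    )
    species.write_text(
        "species_id,genus,growth_habit,is_hemiparasite,life_history\n"
        "SA,GenusA,Forb/herb,False,perennial\n"
        "SB,Castilleja,Forb/herb,True,perennial\n"
        "SC,GenusC,Tree,False,perennial\n"
    )
    plots.write_text(
        "plot_id,latitude,longitude,area_m2,year,park_id,ecoregion_l4\n"
        "P1,40.0,-100.0,400,2005,PK1,E1\n"
        "P2,40.1,-100.1,400,2006,PK1,E1\n"
        "P3,41.0,-101.0,100,2005,PK2,E2\n"
    )
    return cover, species, plots
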