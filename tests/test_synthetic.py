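import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from nullcomm.ingest import classify_growth_form, filter_plots
from nullcomm.metrics import compute_metrics, transform
from nullcomm.synthetic import (
    EFFECT_GAMMA,
    GeneratorConfig,
    generate,
    make_fixture,
    true_effect,
)


class TestReproducibility:
    def test_fixed_seed_byte_identical(self):
        cfg = GeneratorConfig(seed=5, plots_per_park=10, n_species=400, n_focal=20)
        a = generate(cfg, compute_truth=False)
        b = generate(cfg, compute_truth=False)
        for x, y in zip(a[:3], b[:3]):
            assert x.to_csv(index=False) == y.to_csv(index=False)

    def test_different_seeds_differ(self):
        base = dict(plots_per_park=10, n_species=400, n_focal=20)
        a = generate(GeneratorConfig(seed=1, **base), compute_truth=False)
        b = generate(GeneratorConfig(seed=2, **base), compute_truth=False)
        assert not a[0].equals(b[0])


class TestStructure:
    def test_focal_guild_size_and_window(self, default_dataset):
        sp = default_dataset["species"]
        focal = sp.loc[sp.is_hemiparasite]
        assert len(focal) == 78
        assert (focal["growth_form"] == "herbaceous").all()
        lo, hi = default_dataset["focal"].rank_range
        assert hi - lo > 0.5 * len(default_dataset["ra"])  # wide window

    def test_focal_occupancy_near_target(self, default_dataset):
        cover, sp, plots = (
            default_dataset["cover"],
            default_dataset["species"],
            default_dataset["plots"],
        )
        focal = set(sp.loc[sp.is_hemiparasite, "species_id"])
        occ = cover.loc[cover.species_id.isin(focal), "plot_id"].nunique() / len(plots)
        assert occ == pytest.approx(0.13, abs=0.02)

    def test_global_sad_heavy_tailed(self, default_dataset):
        ab = default_dataset["ra"].sort_values("rank")["abundance"].to_numpy()
        top_decile = ab[: max(1, len(ab) // 10)].sum()
        assert top_decile / ab.sum() > 0.5

    def test_output_tables_match_ingest_schema(self, tiny_null, tmp_path):
        from nullcomm.ingest import load_tables
        from nullcomm.synthetic import write_csvs

        cover, species, plots, _ = tiny_null
        write_csvs(tmp_path, cover, species, plots)
        c, s, p, report = load_tables(
            tmp_path / "cover.csv", tmp_path / "species.csv", tmp_path / "plots.csv"
        )
        assert report.n_unknown_plot == 0 and report.n_unknown_species == 0
        assert len(c) == len(cover)

    def test_infeasible_configs_rejected(self):
        with pytest.raises(ValueError, match="focal_occupancy_target"):
            generate(GeneratorConfig(focal_occupancy_target=1.5), compute_truth=False)
        with pytest.raises(ValueError, match="focal rank window"):
            generate(
                GeneratorConfig(n_species=100, n_focal=95), compute_truth=False
            )


class TestEffect:
    def test_zero_effect_decorrelates_cover_and_evenness(self):
        """gamma=0: within ecoregions, ln focal cover carries ~no signal
        about herbaceous evenness (mean correlation over six 5,000-plot
        realisations; single-realisation r has Monte-Carlo sd ~0.04)."""
        rs = []
        for seed in range(31, 37):
            cfg = GeneratorConfig(seed=seed, plots_per_park=125)  # 5,000 plots
            cover, species, plots, truth = generate(cfg, compute_truth=False)
            species = classify_growth_form(species)
            plots, cover = filter_plots(plots, cover)
            mets = compute_metrics(cover, species, plots, forms=("herbaceous",))
            he = mets.set_index("plot_id")["evenness"]
            pp = truth.per_plot.set_index("plot_id").join(
                plots.set_index("plot_id")["ecoregion_l4"]
            )
            sel = (pp.focal_cover > 0) & he.reindex(pp.index).notna()
            df = pd.DataFrame(
                {
                    "x": np.log(pp.focal_cover[sel]),
                    "y": logit(he[sel].clip(1e-6, 1 - 1e-6)),
                    "eco": pp.loc[sel, "ecoregion_l4"],
                }
            )
            centred = df[["x", "y"]] - df.groupby("eco")[["x", "y"]].transform("mean")
            rs.append(np.corrcoef(centred["x"], centred["y"])[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_positive_effect_recovered_within_25pct(self):
        cfg = GeneratorConfig(seed=17, plots_per_park=125, effect_evenness=EFFECT_GAMMA)
        beta_true = true_effect(cfg)
        assert beta_true > 0.1
        cover, species, plots, truth = generate(cfg, compute_truth=False)
        species = classify_growth_form(species)
        plots, cover = filter_plots(plots, cover)
        mets = compute_metrics(cover, species, plots, forms=("herbaceous",))
        from nullcomm.ranks import FocalSet, build_rank_abundance, focal_rank_range
        from nullcomm.inference import run_abundance_analysis

        ra = build_rank_abundance(cover)
        focal_ids = frozenset(species.loc[species.is_hemiparasite, "species_id"])
        focal = FocalSet(focal_ids, "f", focal_rank_range(ra, focal_ids))
        res, _ = run_abundance_analysis(
            cover, mets, plots, focal, [], responses=(("evenness", "herbaceous"),)
        )
        assert res["beta1"].iloc[0] == pytest.approx(beta_true, rel=0.25)

    def test_truth_is_seed_independent(self):
        a = true_effect(GeneratorConfig(seed=1, effect_evenness=EFFECT_GAMMA))
        b = true_effect(GeneratorConfig(seed=2, effect_evenness=EFFECT_GAMMA))
        assert a == b

    def test_richness_effect_raises_richness_on_focal_plots(self):
        base = dict(n_species=600, n_focal=30, plots_per_park=40, seed=3)
        gaps = {}
        for er in (0.0, 3.0):
            cfg = GeneratorConfig(effect_richness=er, **base)
            cover, species, plots, truth = generate(cfg, compute_truth=False)
            s = cover.groupby("plot_id")["species_id"].nunique()
            f = truth.per_plot.set_index("plot_id")["focal_cover"]
            s = s.reindex(f.index).fillna(0)
            gaps[er] = s[f > 0].mean() - s[f == 0].mean()
        # default: focal plots are not richer (beyond the guild's own presence);
        # with the knob on, extra species accrue with focal cover
        assert gaps[3.0] > gaps[0.0] + 2.0


class TestFixtures:
    def test_unknown_fixture_lists_names(self):
        with pytest.raises(ValueError, match="tiny_null"):
            make_fixture("nope")

    def test_fixture_sizes_are_small(self, tiny_null, tiny_effect):
        for cover, species, plots, _ in (tiny_null, tiny_effect):
            assert len(plots) <= 200

    def test_single_taxon_fixture_has_single_taxon_plots(self):
        cover, species, plots, _ = make_fixture("single_taxon_plots")
        counts = cover.groupby("plot_id")["species_id"].nunique()
        assert (counts == 1).sum() >= 3
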