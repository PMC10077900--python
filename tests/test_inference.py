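import math

import numpy as np
import pandas as pd
import pytest

from nullcomm.inference import (
    ModelSpec,
    compute_r2,
    delta_aic,
    empirical_p,
    run_abundance_analysis,
    run_presence_analysis,
)
from nullcomm.lmm import FitResult, LmmError
from nullcomm.metrics import compute_metrics
from nullcomm.pairing import pair_plots
from nullcomm.ingest import classify_growth_form, filter_plots
from nullcomm.ranks import FocalSet, build_rank_abundance, focal_rank_range, sample_null_sets


def make_fit(n_obs=100, vc_sum=3.0, sigma2=6.0, fixed_var=1.0, aic=100.0):
    return FitResult(
        beta=np.array([0.0, 1.0]),
        se=np.array([0.1, 0.1]),
        fixed_names=("intercept", "x"),
        vc={"a": vc_sum},
        sigma2=sigma2,
        loglik=-50.0,
        aic=aic,
        n_obs=n_obs,
        method="reml",
        converged=True,
        theta=np.array([0.5]),
        fixed_var=fixed_var,
    )


class TestComputeR2:
    def test_hand_values(self):
        # v_f=1, v_r=3, v_e=6 -> marginal 0.1, conditional 0.4
        assert compute_r2(make_fit()) == pytest.approx((0.1, 0.4))

    def test_pure_fixed_limit(self):
        assert compute_r2(make_fit(vc_sum=0.0, sigma2=0.0)) == pytest.approx((1.0, 1.0))

    def test_zero_fixed_variance(self):
        m, c = compute_r2(make_fit(fixed_var=0.0))
        assert m == 0.0
        assert c == pytest.approx(3.0 / 9.0)

    def test_zero_total_variance_is_error(self):
        with pytest.raises(ValueError):
            compute_r2(make_fit(vc_sum=0.0, sigma2=0.0, fixed_var=0.0))

    def test_marginal_leq_conditional_leq_one(self, default_dataset):
        d = default_dataset
        res, _ = run_abundance_analysis(
            d["cover"], d["metrics"], d["plots"], d["focal"], [],
            responses=(("evenness", "herbaceous"),),
        )
        row = res.iloc[0]
        assert 0.0 <= row.marginal_r2 <= row.conditional_r2 <= 1.0


class TestEmpiricalP:
    def test_hand_count(self):
        p, _ = empirical_p([1, 2, 3, 4], 2.5)
        assert p == 0.5

    def test_observed_below_all(self):
        p, _ = empirical_p([1, 2, 3, 4], 0.0)
        assert p == 1.0

    def test_observed_above_all_reports_bound(self):
        p, note = empirical_p(list(range(1000)), 1e9)
        assert p == 0.0
        assert "p < 0.001" in note

    def test_empty_ensemble_is_error(self):
        with pytest.raises(ValueError):
            empirical_p([], 1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        nulls = rng.normal(size=200)
        obs = 0.3
        p1, _ = empirical_p(nulls, obs)
        p2, _ = empirical_p(np.exp(nulls), math.exp(obs))
        assert p1 == p2


class TestDeltaAic:
    def test_arithmetic_and_threshold(self):
        assert delta_aic(100.0, 213.0) == pytest.approx(113.0)
        assert delta_aic(100.0, 100.0) == 0.0
        assert delta_aic(105.0, 100.0) == pytest.approx(-5.0)

    def test_antisymmetric(self):
        assert delta_aic(97.0, 103.0) == -delta_aic(103.0, 97.0)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            delta_aic(make_fit(n_obs=100), make_fit(n_obs=99))


class TestAbundanceAnalysis:
    def test_injected_focal_set_reproduces_observed_beta(self, default_dataset):
        """The null path is the focal path with only the set swapped."""
        d = default_dataset
        fake_null = FocalSet(d["focal"].species, "echo", d["focal"].rank_range)
        res, nc = run_abundance_analysis(
            d["cover"], d["metrics"], d["plots"], d["focal"], [fake_null],
            responses=(("evenness", "herbaceous"),),
        )
        assert nc["beta1"].iloc[0] == res["beta1"].iloc[0]
        assert res["empirical_p"].iloc[0] == 1.0  # the single null ties the observed

    def test_results_schema_and_finite(self, default_dataset):
        d = default_dataset
        nulls = sample_null_sets(d["ra"], d["focal"].species, 5, 99)
        res, nc = run_abundance_analysis(
            d["cover"], d["metrics"], d["plots"], d["focal"], nulls,
            responses=(("evenness", "herbaceous"), ("richness", "herbaceous")),
        )
        assert len(res) == 2
        for col in ("beta1", "se", "marginal_r2", "delta_aic", "empirical_p"):
            assert np.isfinite(res[col]).all()
        assert (res["n_null_converged"] + res["n_null_failed"] == 5).all()
        assert len(nc) == res["n_null_converged"].sum()

    def test_evenness_n_below_richness_n_with_single_taxon_plots(self):
        from nullcomm.synthetic import make_fixture

        cover, species, plots, _ = make_fixture("single_taxon_plots")
        species = classify_growth_form(species)
        plots, cover = filter_plots(plots, cover)
        metrics = compute_metrics(cover, species, plots)
        single = metrics.loc[
            (metrics.growth_form == "herbaceous") & (metrics.richness == 1)
        ]
        assert len(single) >= 3
        assert single["evenness"].isna().all()
        ra = build_rank_abundance(cover)
        focal_ids = frozenset(species.loc[species.is_hemiparasite, "species_id"])
        focal = FocalSet(focal_ids, "f", focal_rank_range(ra, focal_ids))
        res, _ = run_abundance_analysis(
            cover, metrics, plots, focal, [],
            responses=(("evenness", "herbaceous"), ("richness", "herbaceous")),
            min_obs=5,
        )
        n = res.set_index("response")["n"]
        assert n["evenness"] <= n["richness"]


@pytest.fixture(scope="module")
def presence_setup(default_dataset):
    pairs, _ = pair_plots(default_dataset["plots"])
    return default_dataset, pairs


class TestPresenceAnalysis:

    def test_runs_and_reports(self, presence_setup):
        d, pairs = presence_setup
        nulls = sample_null_sets(d["ra"], d["focal"].species, 5, 7)
        res, nc = run_presence_analysis(
            pairs, d["cover"], d["metrics"], d["plots"], d["focal"], nulls,
            responses=(("evenness", "herbaceous"),),
        )
        row = res.iloc[0]
        assert row.predictor == "presence"
        assert 0.0 <= row.empirical_p <= 1.0
        assert row.n <= 2 * len(pairs)

    def test_constant_predictor_is_error(self, presence_setup):
        d, pairs = presence_setup
        everything = FocalSet(
            frozenset(d["cover"]["species_id"].unique()), "all", (1, 10**9)
        )
        with pytest.raises(LmmError, match="constant predictor"):
            run_presence_analysis(
                pairs, d["cover"], d["metrics"], d["plots"], everything, [],
                responses=(("evenness", "herbaceous"),),
            )

    def test_empty_pairs_rejected(self, default_dataset):
        d = default_dataset
        with pytest.raises(ValueError, match="empty pair set"):
            run_presence_analysis(
                pd.DataFrame(columns=["plot_a", "plot_b"]),
                d["cover"], d["metrics"], d["plots"], d["focal"], [],
            )
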