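import numpy as np
import pandas as pd
import pytest

import splitcar as sc
from splitcar.graph import icar_marginal_variances
from splitcar.synth import SCENARIOS, make_truth, scenario, simulate_survey


class TestLattices:
    def test_minimal_lattices(self):
        g, geoms = sc.make_lattice_regions(2, 2, 2, 2)
        assert g.n_areas == 8 and g.n_components == 2
        assert len(g.edges) == 8  # two 2x2 rook grids, 4 edges each

    def test_always_two_components(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            g, _ = sc.make_lattice_regions(*rng.integers(2, 6, size=4))
            assert g.n_components == 2

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            sc.make_lattice_regions(1, 2, 2, 2)

    def test_geojson_contiguity_roundtrip(self, tmp_path):
        g, geoms = sc.make_lattice_regions(3, 3, 2, 4)
        rebuilt = sc.build_contiguity_graph(geoms, rule="rook")
        assert rebuilt.edges == g.edges
        assert rebuilt.component_labels == g.component_labels
        # and through an actual GeoJSON file
        b = scenario("homogeneous", lattice=(3, 3, 2, 4))
        b.save(tmp_path)
        items = sc.read_geojson(tmp_path / "areas.geojson")
        again = sc.build_contiguity_graph(items, rule="rook")
        assert again.edges == g.edges


class TestIcarField:
    def test_draws_satisfy_sum_to_zero_per_region(self, two_chains):
        icar = sc.scale_icar(two_chains)
        rng = np.random.default_rng(4)
        labels = np.asarray(two_chains.component_labels)
        for _ in range(20):
            u = sc.sample_icar_field(icar, 2.0, rng)
            for c in range(2):
                assert abs(u[labels == c].sum()) < 1e-10

    def test_empirical_variances_match_scaled_pseudoinverse(self, path3):
        icar = sc.scale_icar(path3)
        target = icar_marginal_variances(icar.structure_matrix, icar.component_labels)
        rng = np.random.default_rng(123)
        draws = np.array([sc.sample_icar_field(icar, 1.0, rng) for _ in range(10_000)])
        emp = draws.var(axis=0)
        assert np.allclose(emp, target, rtol=0.05)

    def test_precision_scaling_law(self, path3):
        icar = sc.scale_icar(path3)
        d1 = np.array([sc.sample_icar_field(icar, 1.0, np.random.default_rng(s)) for s in range(2000)])
        d4 = np.array([sc.sample_icar_field(icar, 4.0, np.random.default_rng(s)) for s in range(2000)])
        assert np.allclose(d1.std(axis=0) / d4.std(axis=0), 2.0, rtol=0.01)


@pytest.fixture(scope="module")
def truth():
    g, geoms = sc.make_lattice_regions(4, 3, 3, 3)
    return make_truth(g, geoms, alpha=-1.0, struct_var=0.05, unstruct_var=0.05,
                      rng=np.random.default_rng(10))


class TestSurveySimulation:

    def test_fixed_seed_reproducible(self, truth):
        r1 = simulate_survey(truth, seed=5, n_psu_per_stratum=20)
        r2 = simulate_survey(truth, seed=5, n_psu_per_stratum=20)
        pd.testing.assert_frame_equal(r1, r2)

    def test_equal_psus_full_coverage_self_weighting(self, truth):
        t = make_truth(truth.graph, truth.geometries, alpha=-1.0, struct_var=0.05,
                       unstruct_var=0.05, rng=np.random.default_rng(11))
        t.urban_share[:] = 1.0  # single stratum per region
        rec = simulate_survey(t, n_psu_per_stratum=40, units_per_psu=10,
                              psu_children_range=(40, 40), unsampled_fraction=0.0, seed=1)
        for region, grp in rec.groupby(rec["area_id"].str[:2]):
            assert grp["weight"].nunique() == 1
        # equal weights: HT estimate equals the sample mean per area
        for area, grp in rec.groupby("area_id"):
            p, _ = sc.ht_prevalence(grp["outcome"], grp["weight"])
            assert p == pytest.approx(grp["outcome"].mean(), abs=1e-12)

    def test_weighted_total_unbiased_for_frame_total(self, truth):
        totals = []
        for s in range(60):
            rec = simulate_survey(truth, seed=s, n_psu_per_stratum=40,
                                  unsampled_fraction=0.0)
            totals.append(rec["weight"].sum())
        # frame total: 12 PSUs per area, sizes uniform on 30..60 -> mean 45
        expected = truth.graph.n_areas * 12 * 45.0
        assert np.mean(totals) == pytest.approx(expected, rel=0.02)

    def test_unsampled_fraction_respected(self, truth):
        rec = simulate_survey(truth, seed=3, unsampled_fraction=0.125)
        n_missing = truth.graph.n_areas - rec["area_id"].nunique()
        assert n_missing == round(0.125 * truth.graph.n_areas)

    def test_requesting_too_large_psu_draw_is_fine_but_zero_prob_not(self, truth):
        # PPS with replacement never exhausts the frame
        rec = simulate_survey(truth, seed=2, n_psu_per_stratum=500)
        assert len(rec) > 0

    def test_design_consistency_mae_decreases_with_psu_size(self, truth):
        maes = []
        for units in (5, 50, 500):
            errs = []
            for s in range(8):
                rec = simulate_survey(truth, seed=1000 + s, units_per_psu=units,
                                      psu_children_range=(600, 800),
                                      n_psu_per_stratum=40, unsampled_fraction=0.0)
                summ = sc.summarize(rec, area_ids=list(truth.graph.area_ids))
                ok = summ["p_hat"].notna()
                errs.append(np.abs(summ["p_hat"][ok] - truth.p_true[ok.to_numpy()]).mean())
            maes.append(np.mean(errs))
        assert maes[0] > maes[1] > maes[2]


class TestScenarios:
    def test_scenario_definitions(self):
        b = scenario("common_baseline", lattice=(3, 2, 2, 2))
        assert b.truth.alpha[0] == b.truth.alpha[1]
        assert b.truth.struct_var[1] / b.truth.struct_var[0] == pytest.approx(4.0)
        b2 = scenario("shifted_baseline", lattice=(3, 2, 2, 2))
        assert b2.truth.alpha[0] != b2.truth.alpha[1]
        b3 = scenario("covariate_effect", lattice=(3, 2, 2, 2))
        assert b3.truth.beta == {"x1": -0.101}
        assert b3.covariates is not None

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("bogus")

    def test_default_seeds_are_documented_and_reproducible(self):
        b1 = scenario("homogeneous", lattice=(3, 2, 2, 2))
        b2 = scenario("homogeneous", lattice=(3, 2, 2, 2))
        assert b1.seed == SCENARIOS["homogeneous"][0]
        pd.testing.assert_frame_equal(b1.records, b2.records)
        assert np.array_equal(b1.truth.p_true, b2.truth.p_true)

    def test_bundle_save_roundtrip(self, tmp_path):
        import json

        b = scenario("covariate_effect", lattice=(3, 2, 2, 2))
        b.save(tmp_path)
        g = sc.read_graph(tmp_path / "graph.txt")
        assert g.n_areas == b.truth.graph.n_areas
        assert g.edges == b.truth.graph.edges
        rec = pd.read_csv(tmp_path / "records.csv")
        assert len(rec) == len(b.records)
        cov = pd.read_csv(tmp_path / "covariates.csv").set_index("area_id")
        assert list(cov.columns) == ["x1"]
        meta = json.loads((tmp_path / "truth.json").read_text())
        assert meta["name"] == "covariate_effect"
        assert np.allclose(meta["p_true"], b.truth.p_true)

    def test_truth_prevalences_strictly_inside_unit_interval(self):
        for name in SCENARIOS:
            b = scenario(name, lattice=(3, 2, 2, 2))
            assert ((b.truth.p_true > 0) & (b.truth.p_true < 1)).all()
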