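"""Population-model grammar, correlation construction, grid, and runner."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from efagrid import (
    PRESETS,
    PopulationModel,
    aggregate,
    build_pattern,
    default_manifest,
    enumerate_grid,
    make_phi,
    parse_code,
    population_correlation,
    run_simulation,
    sample_data,
)
from efagrid.exceptions import ParseError
from efagrid.popsim import (
    DEFAULT_PATTERN_CODES,
    SimulationRecord,
    design_size,
    load_manifest,
    records_to_frame,
)


class TestParseCode:
    def test_simple_code(self):
        skel = parse_code("18|3|6")
        assert (skel.p, skel.m) == (18, 3)
        assert skel.loadings == (0.6,)
        assert skel.n_cross == 0 and not skel.within_between

    def test_within_between_code(self):
        skel = parse_code("18|6|369wb")
        assert (skel.p, skel.m) == (18, 6)
        assert skel.loadings == (0.3, 0.6, 0.9)
        assert skel.within_between

    def test_cross_loading_code(self):
        skel = parse_code("18|3|46|3c")
        assert skel.loadings == (0.4, 0.6)
        assert skel.n_cross == 3

    @pytest.mark.parametrize(
        "bad", ["18-3-6", "18|3", "18|3|06", "18|3|66", "18|3|6|c", "1|1|6", "18|3|6wb"]
    )
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_code(bad)


class TestBuildPattern:
    def test_uniform_block_pattern(self):
        lam = build_pattern(parse_code("18|3|6"))
        assert lam.shape == (18, 3)
        for f in range(3):
            block = lam[f * 6 : (f + 1) * 6]
            np.testing.assert_array_equal(block[:, f], 0.6)
            assert np.all(block[:, [j for j in range(3) if j != f]] == 0)

    def test_two_indicators_per_factor(self):
        lam = build_pattern(parse_code("6|3|6"))
        assert np.all(np.sum(lam != 0, axis=0) == 2)

    def test_between_factor_heterogeneity_cycles_per_factor(self):
        lam = build_pattern(parse_code("18|3|46"))
        nonzero = [set(np.round(lam[lam[:, f] != 0, f], 10)) for f in range(3)]
        assert nonzero == [{0.4}, {0.6}, {0.4}]

    def test_within_between_heterogeneity_cycles_per_indicator(self):
        lam = build_pattern(parse_code("18|6|369wb"))
        block = lam[:3, 0]
        np.testing.assert_allclose(block, [0.3, 0.6, 0.9])

    def test_cross_loadings_fall_on_next_factor(self):
        lam = build_pattern(parse_code("18|3|46|3c"))
        assert np.all(lam[:3, 1] == 0.4)  # smallest loading value
        assert np.sum(np.sum(lam != 0, axis=1) > 1) == 3

    def test_indivisible_design_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_pattern(parse_code("10|3|6"))

    @given(st.sampled_from(DEFAULT_PATTERN_CODES))
    def test_code_round_trips_through_model(self, code):
        skel = parse_code(code)
        model = PopulationModel.from_code(code, 0.3)
        assert model.code == code
        assert (model.p, model.m) == (skel.p, skel.m)
        assert model.loading_set == frozenset(skel.loadings)
        assert model.n_cross == skel.n_cross


class TestPhi:
    def test_scalar_level(self):
        phi = make_phi(3, 0.7)
        np.testing.assert_array_equal(np.diag(phi), 1.0)
        assert np.all(phi[~np.eye(3, dtype=bool)] == 0.7)

    @pytest.mark.parametrize("m", [3, 6])
    def test_mixed_level_is_positive_definite(self, m):
        phi = make_phi(m, "mixed")
        assert np.linalg.eigvalsh(phi)[0] > 0
        assert set(np.round(phi[~np.eye(m, dtype=bool)], 10)) == {0.3, 0.5, 0.7}

    def test_indefinite_phi_rejected(self):
        with pytest.raises(ValueError):
            make_phi(3, -0.9)


class TestPopulationCorrelation:
    def test_one_factor_arithmetic(self):
        model = PopulationModel.from_code("6|3|6", 0.0)
        R = population_correlation(model)
        assert R.values[0, 1] == pytest.approx(0.36)

    def test_between_factor_entry_is_lam_phi_lam(self):
        model = PopulationModel.from_code("12|3|6", 0.7)
        R = population_correlation(model)
        assert R.values[0, 4] == pytest.approx(0.6 * 0.7 * 0.6)

    def test_diagonal_is_exactly_one(self):
        model = PopulationModel.from_code("18|6|369wb", "mixed")
        R = population_correlation(model)
        assert np.all(np.diag(R.values) == 1.0)

    def test_orthogonal_block_closed_form(self):
        model = PopulationModel.from_code("12|3|46", 0.0)
        R = population_correlation(model).values
        lam = model.Lambda
        within = lam @ lam.T
        np.fill_diagonal(within, 1.0)
        np.testing.assert_allclose(R, within, atol=1e-12)


class TestSampling:
    def test_determinism_under_seed(self):
        R = PopulationModel.from_code("12|3|6", 0.3).correlation()
        a = sample_data(R, 50, seed=7)
        b = sample_data(R, 50, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_large_sample_matches_population(self):
        R = PopulationModel.from_code("12|3|6", 0.7).correlation()
        x = sample_data(R, 100_000, seed=3)
        emp = np.corrcoef(x, rowvar=False)
        assert emp[0, 4] == pytest.approx(0.252, abs=0.01)

    def test_unit_population_sd(self):
        R = PopulationModel.from_code("12|3|6", 0.3).correlation()
        x = sample_data(R, 10_000, seed=5)
        assert np.all(np.abs(x.std(axis=0, ddof=1) - 1.0) < 0.05)


class TestGrid:
    def test_default_grid_has_192_members(self):
        assert len(enumerate_grid()) == 192

    def test_restricting_one_dimension_scales_the_count(self):
        assert len(enumerate_grid({"init_comm": ("smc",)})) == 64

    def test_labels_are_unique(self):
        labels = [s.label for s in enumerate_grid()]
        assert len(set(labels)) == len(labels)

    @pytest.mark.parametrize("name", ["psych_smc", "psych_unity", "spss", "best"])
    def test_presets_are_grid_members(self, name):
        keys = {s.settings_key() for s in enumerate_grid()}
        assert PRESETS[name].settings_key() in keys

    def test_preset_settings_match_their_programs(self):
        psych = PRESETS["psych_smc"]
        assert (psych.paf.criterion_type, psych.paf.abs_eigen) == ("sum", False)
        assert (psych.rot.varimax_type, psych.rot.p_type) == ("svd", "unnorm")
        assert psych.paf.smc_fail_fallback == "unity"
        spss = PRESETS["spss"]
        assert (spss.paf.criterion_type, spss.paf.abs_eigen) == ("max_individual", True)
        assert (spss.rot.varimax_type, spss.rot.p_type) == ("kaiser", "norm")
        assert (spss.paf.smc_fail_fallback, spss.nonpd) == ("mac", "abort")
        best = PRESETS["best"]
        assert (best.paf.init_comm, best.paf.criterion_type) == ("smc", "sum")
        assert best.paf.abs_eigen and best.paf.criterion == 1e-3
        assert (best.rot.varimax_type, best.rot.p_type, best.rot.k) == ("kaiser", "norm", 4)


class TestDesign:
    def test_default_manifest_has_108_models(self):
        assert len(default_manifest()) == 108

    def test_full_design_enumerates_216000_data_sets(self):
        assert design_size(len(default_manifest()), 2, 1000) == 216_000

    def test_manifest_yaml_round_trip(self, tmp_path):
        path = tmp_path / "manifest.yaml"
        path.write_text("codes: ['6|3|6', '12|3|6']\nphi_levels: [0.0, mixed]\n")
        models = load_manifest(path)
        assert len(models) == 4
        assert {m.code for m in models} == {"6|3|6", "12|3|6"}


class TestRunner:
    def test_record_bookkeeping(self):
        models = [PopulationModel.from_code("6|3|6", 0.0)]
        specs = [PRESETS["best"], PRESETS["spss"], PRESETS["psych_unity"]]
        records = run_simulation(models, [120], reps=2, specs=specs, seed=1)
        assert len(records) == 6
        df = records_to_frame(records)
        assert set(df["implementation_label"]) == {"best", "spss", "psych_unity"}

    def test_reproducible_under_master_seed(self):
        models = [PopulationModel.from_code("6|3|6", 0.3)]
        a = run_simulation(models, [100], reps=2, specs=[PRESETS["best"]], seed=9)
        b = run_simulation(models, [100], reps=2, specs=[PRESETS["best"]], seed=9)
        assert a == b

    def test_subset_of_design_reuses_identical_draws(self):
        models = [PopulationModel.from_code("6|3|6", 0.3)]
        full = run_simulation(models, [100], reps=3, specs=[PRESETS["best"]], seed=9)
        sub = run_simulation(models, [100], reps=2, specs=[PRESETS["best"]], seed=9)
        assert full[:2] == sub

    def test_aggregate_props_and_tie_break(self):
        rec = lambda label, r, hw, ce: SimulationRecord(
            model_code="6|3|6",
            phi_label="0",
            n=100,
            replicate=0,
            seed=0,
            implementation_label=label,
            rmse=r,
            heywood=hw,
            correspondence_errors=ce,
            negative_eigenvalue_encountered=False,
            converged=True,
        )
        records = [
            rec("b_impl", 0.1, True, 1),
            rec("b_impl", 0.1, False, 0),
            rec("a_impl", 0.1, False, 0),
            rec("a_impl", 0.1, True, 2),
        ]
        agg = aggregate(records)
        assert list(agg["implementation_label"]) == ["a_impl", "b_impl"]  # tie -> label
        assert np.allclose(agg["heywood_prop"], 0.5)
        assert np.allclose(agg["correspondence_error_prop"], 0.5)
        assert np.allclose(agg["mrmse"], 0.1)
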