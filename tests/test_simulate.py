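"""Synthetic populations: protocol compliance, reproducibility, closure."""

import math

import numpy as np
import pytest
from scipy import stats

from stembark import (
    SimulationConfig,
    fit_power_two_predictor,
    predict_height,
    simulate_population,
    simulate_sections,
    synthetic_dbh_table,
    synthetic_power_table,
    to_observation_tables,
)
from stembark.simulate import read_population, write_population


def noiseless_config(species, n_trees=20, seed=0):
    return SimulationConfig.for_species(
        species, seed=seed, n_trees=n_trees,
        noise_height_m=0.0, noise_dbh_mm=0.0, noise_radius_cm=0.0, noise_thickness_mm=0.0,
    )


class TestPopulationDraw:
    def test_published_sample_sizes_are_defaults(self):
        expected = {"common_aspen": 180, "goat_willow": 120, "rowan": 100, "sycamore": 200}
        for sp, n in expected.items():
            assert SimulationConfig.for_species(sp).n_trees == n

    def test_d0_distribution_matches_truncated_normal_oracle(self):
        """Large-sample mean of D0 agrees with the truncated-normal mean."""
        cfg = SimulationConfig.for_species("common_aspen", seed=123, n_trees=10_000)
        trees = simulate_population(cfg)
        d0 = np.array([t.d0_mm for t in trees])
        a = (cfg.d0_min_mm - cfg.d0_mean_mm) / cfg.d0_sd_mm
        oracle_mean = stats.truncnorm.mean(a, np.inf, loc=cfg.d0_mean_mm, scale=cfg.d0_sd_mm)
        assert d0.mean() == pytest.approx(oracle_mean, rel=0.02)
        assert d0.min() >= cfg.d0_min_mm

    def test_single_tree_population_has_protocol_minimum_sections(self):
        trees = simulate_population(noiseless_config("rowan", n_trees=1))
        assert len(trees) == 1
        assert len(trees[0].sections) >= 4

    def test_dbh_present_iff_above_breast_height(self):
        cfg = SimulationConfig.for_species("sycamore", seed=5, n_trees=200)
        for t in simulate_population(cfg):
            assert (t.dbh_mm is not None) == (t.height_m > 1.3)


class TestSectionRules:
    @pytest.mark.parametrize(
        "height_m, n_expected, length_expected",
        [(2.0, 4, 50.0), (6.0, 6, 100.0), (0.5, 4, 12.5)],
    )
    def test_count_and_equal_lengths(self, height_m, n_expected, length_expected):
        from stembark.simulate import SimulatedTree

        cfg = noiseless_config("common_aspen")
        tree = SimulatedTree("x", "common_aspen", 40.0, height_m, None)
        sections = simulate_sections(tree, cfg)
        assert len(sections) == n_expected
        for s in sections:
            assert (s.upper_cm - s.lower_cm) == pytest.approx(length_expected)
            assert s.upper_cm - s.lower_cm <= 100.0 + 1e-9

    def test_protocol_compliance_with_noise(self):
        cfg = SimulationConfig.for_species("goat_willow", seed=77, n_trees=50)
        for t in simulate_population(cfg):
            assert len(t.sections) >= 4
            # contiguous cover from the ground to the stem tip
            assert t.sections[0].lower_cm == 0.0
            assert t.sections[-1].upper_cm == pytest.approx(t.height_m * 100.0)
            for a, b in zip(t.sections, t.sections[1:]):
                assert a.upper_cm == pytest.approx(b.lower_cm)
            for s in t.sections:
                for over, under in zip(s.d_over_mm, s.d_under_mm):
                    assert under < over

    def test_zero_noise_lies_exactly_on_generating_curves(self):
        cfg = noiseless_config("common_aspen", n_trees=10, seed=3)
        lib = cfg.generating_models
        for t in simulate_population(cfg):
            expected_h = float(predict_height(lib.height_model, t.d0_mm))
            assert t.height_m == pytest.approx(max(expected_h, 0.3), rel=1e-12)
            for s in t.sections:
                for hg, d_over, d_under in zip(s.hg_cm, s.d_over_mm, s.d_under_mm):
                    back_t = (d_over - d_under) / 2.0
                    expected_t = lib.thickness_model.b0 * t.d0_mm**lib.thickness_model.b1 * max(hg, 1.0)**lib.thickness_model.b2
                    assert back_t == pytest.approx(expected_t, rel=1e-12)


class TestObservationTables:
    def test_row_counts(self):
        cfg = noiseless_config("goat_willow", n_trees=15, seed=9)
        trees = simulate_population(cfg)
        tables = to_observation_tables(trees)
        assert len(tables["height_m"]) == 15
        expected_rows = sum(
            sum(1 for s in t.sections for hg in s.hg_cm if 1.0 <= hg <= 250.0)
            for t in trees
        )
        assert len(tables["radius_cm"]) == expected_rows
        assert len(tables["thickness_mm"]) == expected_rows

    def test_diameter_convention_doubles_thickness_response(self):
        trees = simulate_population(noiseless_config("rowan", n_trees=5, seed=2))
        radial = to_observation_tables(trees, "radial")["thickness_mm"]
        diam = to_observation_tables(trees, "diameter")["thickness_mm"]
        assert np.allclose(diam.data["response"], 2.0 * radial.data["response"])

    def test_zero_noise_round_trip_recovers_radius_model(self):
        cfg = noiseless_config("sycamore", n_trees=30, seed=8)
        tables = to_observation_tables(simulate_population(cfg))
        fm = fit_power_two_predictor(tables["radius_cm"])
        m = cfg.generating_models.radius_model
        for name, truth in (("b0", m.b0), ("b1", m.b1), ("b2", m.b2)):
            assert fm.coefficients[name] == pytest.approx(truth, rel=1e-6)


class TestReproducibility:
    def test_identical_configs_yield_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig.for_species("common_aspen", seed=31, n_trees=25)
        a, b = tmp_path / "a", tmp_path / "b"
        write_population(simulate_population(cfg), a)
        write_population(simulate_population(cfg), b)
        for name in ("trees.csv", "sections.csv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_population_round_trips_through_csv(self, tmp_path):
        cfg = SimulationConfig.for_species("rowan", seed=4, n_trees=10)
        trees = simulate_population(cfg)
        write_population(trees, tmp_path)
        back = read_population(tmp_path)
        assert back == trees


class TestRecoveryAtScale:
    def test_replicate_mean_recovers_power_coefficients(self):
        """Over replicate populations at the published sample size and
        noise level, the mean NLS estimate of every power-model
        coefficient sits within three published standard errors of the
        generating value.  (Individual replicates scatter more: the
        estimator's sampling SD at this design is comparable to, and for
        the height exponents larger than, the published standard
        errors.)"""
        reps = 15
        lib = SimulationConfig.for_species("common_aspen").generating_models
        est = {"radius_cm": [], "thickness_mm": []}
        for r in range(reps):
            cfg = SimulationConfig.for_species("common_aspen", seed=1000 + r)
            tables = to_observation_tables(simulate_population(cfg))
            for kind in est:
                fm = fit_power_two_predictor(tables[kind])
                est[kind].append([fm.coefficients[k] for k in ("b0", "b1", "b2")])
        for kind, model in (("radius_cm", lib.radius_model), ("thickness_mm", lib.thickness_model)):
            mean = np.mean(est[kind], axis=0)
            for i, name in enumerate(("b0", "b1", "b2")):
                truth, se = getattr(model, name), model.se[name]
                assert abs(mean[i] - truth) < 3 * se, (kind, name, mean[i])


class TestDirectTables:
    def test_power_table_zero_noise_is_exact(self, aspen):
        table = synthetic_power_table(
            aspen.radius_model, "radius_cm", 50, 31.9, 21.1, seed=6
        )
        d0 = table.data["d0_mm"].to_numpy()
        hg = table.data["hg_cm"].to_numpy()
        m = aspen.radius_model
        assert np.allclose(table.data["response"], m.b0 * d0**m.b1 * hg**m.b2)

    def test_power_table_noise_is_positive_and_calibrated(self, aspen):
        sd = math.sqrt(0.287)
        table = synthetic_power_table(
            aspen.thickness_model, "thickness_mm", 4000, 31.9, 21.1, seed=10, noise_sd=sd
        )
        assert (table.data["response"] > 0).all()
        m = aspen.thickness_model
        mu = m.b0 * table.data["d0_mm"] ** m.b1 * table.data["hg_cm"] ** m.b2
        resid = table.data["response"] - mu
        # truncation inflates the mean slightly but the scale stays close
        assert resid.std() == pytest.approx(sd, rel=0.15)

    def test_dbh_table_only_contains_trees_above_breast_height(self, aspen):
        table = synthetic_dbh_table(aspen, 100, 31.9, 21.1, seed=12, noise_sd=0.0)
        assert len(table) == 100
        heights = predict_height(aspen.height_model, table.data["d0_mm"].to_numpy())
        assert (heights > 1.3).all()
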