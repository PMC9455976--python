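"""Synthetic cohort generator: study design, determinism, effect structure."""

import numpy as np
import pytest

from honeyprint import (
    BandSpec,
    ClassEffect,
    GeneratorConfig,
    default_generator_config,
    default_study_design,
    generate_cohort,
    generate_spectrum,
    informative_indices,
    noise_free_template,
    trim_window,
)
from honeyprint.synthetic import config_from_yaml, config_to_yaml, load_preset


class TestStudyDesign:
    def test_total_and_factor_margins(self):
        d = default_study_design()
        assert d.n_samples == 109
        assert d.marginal("year") == {"2020": 60, "2021": 49}
        assert d.marginal("region") == {"Transylvania": 34, "Others": 20}
        assert d.marginal("botanical") == {
            "acacia": 41, "linden": 30, "colza": 18, "honeydew": 20,
        }

    def test_botanical_by_year_cells(self):
        d = default_study_design()
        by = {}
        for (bot, year, _), cnt in d.counts.items():
            by[(bot, year)] = by.get((bot, year), 0) + cnt
        assert by[("acacia", "2020")] == 20 and by[("acacia", "2021")] == 21
        assert by[("linden", "2020")] == 19 and by[("linden", "2021")] == 11
        assert by[("colza", "2020")] == 8 and by[("colza", "2021")] == 10
        assert by[("honeydew", "2020")] == 13 and by[("honeydew", "2021")] == 7

    def test_region_labelled_count_is_54(self):
        d = default_study_design()
        labelled = sum(c for (b, y, r), c in d.counts.items() if r is not None)
        assert labelled == 54


def _quiet(cfg):
    cfg.noise_sd = 0.0
    cfg.baseline_sd = 0.0
    cfg.scatter_sd = 0.0
    cfg.within_class_amp_sd = 0.0
    cfg.effect_strength_sd = 0.0
    return cfg


class TestGenerateSpectrum:
    def test_single_noise_free_band_is_exact_gaussian(self):
        cfg = _quiet(GeneratorConfig(
            grid_start=500, grid_stop=700, grid_spacing=1.0,
            band_library=[BandSpec(600.0, 10.0, 0.5)],
        ))
        row = generate_spectrum(cfg, {}, np.random.default_rng(0))
        grid = cfg.grid()
        inside = np.abs(grid - 600) <= 40
        expected = 0.5 * np.exp(-0.5 * ((grid - 600) / 10.0) ** 2)
        assert np.allclose(row[inside], expected[inside])
        assert np.all(row[~inside] == 0)
        assert row[grid == 600][0] == pytest.approx(0.5)

    def test_same_rng_state_gives_identical_rows(self):
        cfg = default_generator_config()
        labels = {"botanical": "acacia", "year": "2020", "region": None}
        r1 = generate_spectrum(cfg, labels, np.random.default_rng(5))
        r2 = generate_spectrum(cfg, labels, np.random.default_rng(5))
        assert np.array_equal(r1, r2)

    def test_amplitude_multiplier_doubles_peak(self):
        band = BandSpec(600.0, 10.0, 0.4)
        cfg = _quiet(GeneratorConfig(
            grid_start=500, grid_stop=700, grid_spacing=1.0,
            band_library=[band],
            effects=[ClassEffect("year", "2021", 0, amplitude_multiplier=2.0)],
        ))
        base = generate_spectrum(cfg, {"year": "2020"}, np.random.default_rng(0))
        doubled = generate_spectrum(cfg, {"year": "2021"}, np.random.default_rng(0))
        grid = cfg.grid()
        peak = grid == 600
        assert doubled[peak][0] == pytest.approx(2 * base[peak][0])

    def test_effect_localisation(self):
        # with all nuisances off, samples differing only in year differ only
        # within +/- 4 sigma of the year-affected bands
        cfg = _quiet(default_generator_config())
        a = noise_free_template(cfg, {"botanical": "acacia", "year": "2020"})
        b = noise_free_template(cfg, {"botanical": "acacia", "year": "2021"})
        grid = cfg.grid()
        differ = np.abs(a - b) > 1e-15
        allowed = np.zeros_like(differ)
        year_bands = {e.band_index for e in cfg.effects if e.factor == "year"}
        for i in year_bands:
            band = cfg.band_library[i]
            allowed |= np.abs(grid - band.center) <= 4 * band.width
        assert not np.any(differ & ~allowed)


class TestGenerateCohort:
    def test_default_cohort_shape_and_determinism(self):
        cfg = default_generator_config()
        c1 = generate_cohort(cfg, default_study_design())
        c2 = generate_cohort(cfg, default_study_design())
        assert c1.n_samples == 109
        assert np.array_equal(c1.absorbance, c2.absorbance)
        assert c1.meta.equals(c2.meta)

    def test_different_seed_changes_data(self):
        base = generate_cohort(default_generator_config(), default_study_design())
        other = generate_cohort(default_generator_config(seed=7), default_study_design())
        assert not np.array_equal(base.absorbance, other.absorbance)

    def test_sample_order_is_shuffled_not_grouped(self):
        cohort = generate_cohort(default_generator_config(), default_study_design())
        bot = cohort.meta["botanical"].to_numpy()
        changes = (bot[1:] != bot[:-1]).sum()
        assert changes > 20  # class-sorted order would give exactly 3

    def test_fingerprint_window_has_1246_variables(self):
        cohort = generate_cohort(default_generator_config(), default_study_design())
        assert trim_window(cohort, 550, 1775).n_variables == 1246

    def test_class_mean_converges_to_template(self):
        cfg = default_generator_config()
        labels = {"botanical": "acacia", "year": "2020", "region": None}
        template = noise_free_template(cfg, labels)
        rng = np.random.default_rng(123)
        n = 500
        rows = np.vstack([generate_spectrum(cfg, labels, rng) for _ in range(n)])
        mean = rows.mean(axis=0)
        se = rows.std(axis=0, ddof=1) / np.sqrt(n)
        z = np.abs(mean - template) / np.maximum(se, 1e-12)
        # pointwise 3-SE holds for ~99.7% of points by construction; allow the
        # expected handful of chance exceedances but no gross deviation
        assert np.mean(z <= 3) >= 0.99
        assert z.max() <= 6


class TestInformativeIndices:
    def test_counts_per_factor(self):
        cfg = default_generator_config()
        assert informative_indices(cfg, "year").size == 40
        assert informative_indices(cfg, "botanical").size == 50
        assert informative_indices(cfg, "region").size == 60

    def test_sets_fall_inside_reported_marker_regions(self):
        cfg = default_generator_config()
        grid = cfg.grid()
        regions = {
            "year": [(550, 700), (1050, 1100), (1404, 1434)],
            "botanical": [(550, 1000), (1550, 1700)],
            "region": [(550, 700), (695, 725), (795, 825), (855, 885), (1165, 1195)],
        }
        for factor, regs in regions.items():
            wn = grid[informative_indices(cfg, factor)]
            ok = np.zeros(wn.size, bool)
            for lo, hi in regs:
                ok |= (wn >= lo) & (wn <= hi)
            assert ok.all(), factor


def test_config_yaml_round_trip(tmp_path):
    cfg = default_generator_config()
    path = tmp_path / "gen.yaml"
    config_to_yaml(cfg, path)
    back = config_from_yaml(path)
    assert back.seed == cfg.seed
    assert back.band_library == cfg.band_library
    assert back.effects == cfg.effects
    assert back.noise_sd == cfg.noise_sd


def test_shipped_study_preset_matches_defaults():
    cfg = default_generator_config()
    preset = load_preset("study")
    assert preset.band_library == cfg.band_library
    assert preset.effects == cfg.effects
    assert preset.seed == cfg.seed
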