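"""Synthetic survey generator: determinism, calibration, degenerate configs."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from trophos import (
    ConfigurationError,
    default_scenario,
    generate_dataset,
    generate_isotopes,
    generate_specimens,
    generate_stomachs,
    read_dataset,
    write_dataset,
)
from trophos.types import (
    isotopes_to_frame,
    specimens_to_frame,
    stomachs_to_frame,
)


def single_cell_config(n=100, species="T. mediterraneus", area="North",
                       sex="ND", **overrides):
    base = default_scenario(seed=7)
    cfg = replace(
        base,
        cell_sizes={(species, area, "inshore", sex): n},
        **overrides,
    )
    cfg.validate()
    return cfg


class TestDeterminism:
    def test_identical_config_identical_dataset(self, default_config):
        a = generate_dataset(default_config)
        b = generate_dataset(default_config)
        assert specimens_to_frame(a.specimens).equals(
            specimens_to_frame(b.specimens)
        )
        assert stomachs_to_frame(a.stomachs).equals(stomachs_to_frame(b.stomachs))
        assert isotopes_to_frame(a.isotopes).equals(isotopes_to_frame(b.isotopes))

    def test_streams_independent_of_call_order(self, default_config):
        specimens = generate_specimens(default_config)
        iso_first = generate_isotopes(specimens, default_config)
        generate_stomachs(specimens, default_config)
        iso_second = generate_isotopes(specimens, default_config)
        assert iso_first == iso_second

    def test_round_trip_through_csv(self, tmp_path, default_config):
        ds = generate_dataset(default_config)
        write_dataset(ds, tmp_path)
        back = read_dataset(tmp_path)
        assert back.specimens == ds.specimens
        assert back.isotopes[0].specimen_id == ds.isotopes[0].specimen_id
        assert len(back.stomachs) == len(ds.stomachs)
        assert back.stomachs[0].prey == ds.stomachs[0].prey
        assert back.config.to_dict() == ds.config.to_dict()


class TestSpecimens:
    def test_default_scenario_sample_sizes(self, default_dataset):
        counts = Counter(s.species for s in default_dataset.specimens)
        assert counts == {
            "S. colias": 62,
            "S. scombrus": 16,
            "T. mediterraneus": 93,
            "T. trachurus": 42,
        }

    def test_per_cell_counts_exact(self, default_config, default_dataset):
        cells = Counter(
            (s.species, s.area, s.stratum, s.sex)
            for s in default_dataset.specimens
        )
        assert dict(cells) == default_config.cell_sizes

    def test_all_zero_cells_gives_empty_list(self, default_config):
        cfg = replace(
            default_config,
            cell_sizes={k: 0 for k in default_config.cell_sizes},
        )
        assert generate_specimens(cfg) == []

    def test_tl_within_bands_and_weight_law(self, default_config,
                                            default_dataset):
        for s in default_dataset.specimens:
            lo, hi = default_config.size_bands[s.size_class]
            assert lo - 0.05 <= s.tl_cm <= hi + 0.05  # 0.1 cm rounding
            expected_ww = default_config.lw_a * s.tl_cm**default_config.lw_b
            assert s.ww_g == pytest.approx(expected_ww, abs=0.5)

    def test_sexed_adults_never_small(self, default_dataset):
        for s in default_dataset.specimens:
            if s.sex != "ND":
                assert s.size_class != "small"

    def test_size_class_proportions_within_three_se(self):
        n = 1000
        mix = (0.5, 0.5, 0.0)
        cfg = single_cell_config(
            n=n, size_class_mix={"T. mediterraneus": mix}
        )
        specimens = generate_specimens(cfg)
        counts = Counter(s.size_class for s in specimens)
        for cls, p in zip(("small", "medium", "large"), mix):
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(counts.get(cls, 0) / n - p) <= max(3 * se, 1e-9)


class TestStomachs:
    def test_empty_rate_one_means_all_empty(self):
        cfg = single_cell_config(empty_rate={"T. mediterraneus": 1.0})
        stomachs = generate_stomachs(generate_specimens(cfg), cfg)
        assert all(s.empty for s in stomachs)
        assert all(s.fullness < 0.5 for s in stomachs)

    def test_single_taxon_profile(self):
        cfg = single_cell_config(
            empty_rate={"T. mediterraneus": 0.0},
            prey_profiles={("T. mediterraneus", "North"): {"Salpidae": 1.0}},
        )
        stomachs = generate_stomachs(generate_specimens(cfg), cfg)
        for s in stomachs:
            assert {p.taxon for p in s.prey} == {"Salpidae"}

    def test_fullness_bounded_by_cap(self, default_config, default_dataset):
        for s in default_dataset.stomachs:
            assert s.fullness <= default_config.fullness_cap + 1e-9

    def test_digestion_grades_valid(self, default_dataset):
        grades = {p.digestion for s in default_dataset.stomachs for p in s.prey}
        assert grades <= {0, 1, 2, 3}

    def test_empty_count_binomial(self):
        """Observed empty-stomach totals match Binomial(n, empty_rate)."""
        from scipy import stats

        rate = 16 / 93
        n_seeds = 50
        total = 0
        for seed in range(n_seeds):
            cfg = replace(default_scenario(seed=seed))
            specimens = [
                s for s in generate_specimens(cfg)
                if s.species == "T. mediterraneus"
            ]
            stomachs = generate_stomachs(specimens, cfg)
            total += sum(s.empty for s in stomachs)
        n_trials = n_seeds * 93
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_trials, rate)
        assert lo <= total <= hi


class TestIsotopes:
    def test_noiseless_limit_equals_cell_mean(self):
        zero_cov = ((0.0, 0.0), (0.0, 0.0))
        cfg = single_cell_config(
            isotope_params={("T. mediterraneus", "North"): ((-19.0, 9.4),
                                                            zero_cov)},
            tl_slopes={"T. mediterraneus": (0.0, 0.0)},
        )
        isotopes = generate_isotopes(generate_specimens(cfg), cfg)
        assert all(i.d13c_raw == pytest.approx(-19.0) for i in isotopes)
        assert all(i.d15n == pytest.approx(9.4) for i in isotopes)

    def test_covariance_recovery_large_n(self):
        cfg = single_cell_config(
            n=5000,
            isotope_params={("T. mediterraneus", "North"): ((0.0, 0.0),
                                                            ((1.0, 0.0),
                                                             (0.0, 1.0)))},
            tl_slopes={"T. mediterraneus": (0.0, 0.0)},
        )
        isotopes = generate_isotopes(generate_specimens(cfg), cfg)
        xy = np.array([[i.d13c_raw, i.d15n] for i in isotopes])
        cov = np.cov(xy, rowvar=False)
        np.testing.assert_allclose(cov, np.eye(2), atol=0.05)

    def test_cell_mean_recovery_within_three_se(self):
        cfg = single_cell_config(n=2000, tl_slopes={"T. mediterraneus": (0.0, 0.0)})
        isotopes = generate_isotopes(generate_specimens(cfg), cfg)
        mean, cov = cfg.isotope_params[("T. mediterraneus", "North")]
        xy = np.array([[i.d13c_raw, i.d15n] for i in isotopes])
        for axis in (0, 1):
            se = np.sqrt(np.asarray(cov)[axis, axis] / len(xy))
            assert abs(xy[:, axis].mean() - mean[axis]) <= 3 * se

    def test_raw_values_uncorrected(self, default_dataset):
        assert all(i.d13c_corrected is None for i in default_dataset.isotopes)


class TestValidation:
    def test_negative_cell_size(self, default_config):
        cfg = replace(
            default_config,
            cell_sizes={**default_config.cell_sizes,
                        ("S. colias", "North", "offshore", "M"): -1},
        )
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_non_psd_covariance(self, default_config):
        bad = ((1.0, 2.0), (2.0, 1.0))  # eigenvalues -1, 3
        cfg = replace(
            default_config,
            isotope_params={**default_config.isotope_params,
                            ("S. colias", "North"): ((-19.0, 9.0), bad)},
        )
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_unknown_taxon_in_profile(self, default_config):
        cfg = replace(
            default_config,
            prey_profiles={**default_config.prey_profiles,
                           ("S. colias", "North"): {"Kraken": 1.0}},
        )
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_profile_must_sum_to_one(self, default_config):
        cfg = replace(
            default_config,
            prey_profiles={**default_config.prey_profiles,
                           ("S. colias", "North"): {"Salpidae": 0.5}},
        )
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_missing_isotope_params_for_populated_cell(self, default_config):
        params = dict(default_config.isotope_params)
        del params[("S. colias", "North")]
        cfg = replace(default_config, isotope_params=params)
        with pytest.raises(ConfigurationError):
            cfg.validate()
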