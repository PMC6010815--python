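"""Seeded generators: determinism, structure, and parameter links."""

import datetime

import numpy as np
import pandas as pd
import pytest

from isobarrier.barrier_metrics import overlap_days
from isobarrier.bee_vision import VisionModel, chromatic_distance, locus_of
from isobarrier.constancy import forager_constancy, tabulate_transitions
from isobarrier.errors import InvalidInputError
from isobarrier.synthetic_data import (CrossingCellConfig, SimulationConfig,
                                       SpeciesConfig, SpectrumConfig,
                                       expected_relative_success,
                                       simulate_crossings, simulate_foraging,
                                       simulate_phenology, simulate_spectra,
                                       simulate_study)

D = datetime.date


def small_config(**overrides):
    base = SimulationConfig(
        seed=5,
        n_plants={"white": 10, "pink": 8},
        species=(SpeciesConfig("apis_like", kappa=0.9, n_foragers=8,
                               mean_bout_length=8.0),),
        n_per_cell=10,
        n_spectra_per_form=2,
    )
    return base.replace(**overrides)


def test_full_study_deterministic_under_seed():
    a = simulate_study(small_config())
    b = simulate_study(small_config())
    assert a["intervals"] == b["intervals"]
    pd.testing.assert_frame_equal(a["schedules"], b["schedules"])
    assert a["bouts"] == b["bouts"]
    pd.testing.assert_frame_equal(a["crossings"], b["crossings"])
    for form in a["spectra"]:
        for sa, sb in zip(a["spectra"][form], b["spectra"][form]):
            assert np.array_equal(sa.values, sb.values)


def test_different_seeds_differ():
    a = simulate_study(small_config())
    b = simulate_study(small_config(seed=6))
    assert not a["crossings"].equals(b["crossings"])


class TestPhenology:
    def test_point_window_zero_spread_is_deterministic(self):
        cfg = small_config(
            season_windows={"white": (D(2016, 7, 24), D(2016, 7, 24)),
                            "pink": (D(2016, 7, 31), D(2016, 7, 31))},
            flower_lifespan_days=48, lifespan_sd_days=0.0)
        intervals, sched = simulate_phenology(cfg)
        assert intervals["white"].first_day == D(2016, 7, 24)
        assert intervals["white"].last_day == D(2016, 9, 9)
        assert sched.groupby("form")["first_day"].nunique().max() == 1

    def test_disjoint_windows_give_zero_overlap(self):
        cfg = small_config(
            season_windows={"white": (D(2016, 5, 1), D(2016, 5, 5)),
                            "pink": (D(2016, 8, 1), D(2016, 8, 5))},
            flower_lifespan_days=3, lifespan_sd_days=0.0)
        intervals, _ = simulate_phenology(cfg)
        shared, _ = overlap_days(intervals["white"], intervals["pink"])
        assert shared == 0

    def test_empty_window_rejected(self):
        cfg = small_config(
            season_windows={"white": (D(2016, 8, 5), D(2016, 8, 1)),
                            "pink": (D(2016, 8, 1), D(2016, 8, 5))})
        with pytest.raises(InvalidInputError):
            simulate_phenology(cfg)


class TestForaging:
    def test_fully_constant_foragers_never_switch(self):
        cfg = small_config(species=(SpeciesConfig("sp", kappa=1.0, n_foragers=10,
                                                  mean_bout_length=10.0),))
        bouts = simulate_foraging(cfg)
        # score against the 50:50 array so pure-form foragers are defined
        records = forager_constancy(bouts, cfg.forms, expected_share=0.5)
        defined = [r.ci for r in records if r.n_transitions >= 1]
        assert defined and all(ci == pytest.approx(1.0) for ci in defined)

    def test_availability_random_foraging_has_near_zero_mean_ci(self):
        cfg = small_config(species=(SpeciesConfig("sp", kappa=0.0, n_foragers=300,
                                                  mean_bout_length=12.0),), seed=11)
        records = forager_constancy(simulate_foraging(cfg), cfg.forms,
                                    expected_share=0.5)
        cis = np.array([r.ci for r in records])
        assert abs(np.nanmean(cis)) < 0.05

    def test_mean_ci_increases_with_kappa(self):
        means = []
        for kappa in (0.6, 0.9):
            cfg = small_config(species=(SpeciesConfig("sp", kappa=kappa,
                                                      n_foragers=150,
                                                      mean_bout_length=10.0),),
                               seed=3)
            records = forager_constancy(simulate_foraging(cfg), cfg.forms,
                                        expected_share=0.5)
            means.append(np.nanmean([r.ci for r in records]))
        assert means[1] > means[0]

    def test_transition_ratio_matches_markov_expectation(self):
        kappa = 0.8
        cfg = small_config(species=(SpeciesConfig("sp", kappa=kappa,
                                                  n_foragers=400,
                                                  mean_bout_length=12.0),),
                           seed=9)
        table, _ = tabulate_transitions(simulate_foraging(cfg), cfg.forms)
        h_hat = table.count("pink", "white") / table.count("white", "white")
        assert h_hat == pytest.approx(expected_relative_success(kappa), rel=0.2)


class TestCrossings:
    def test_zero_fruit_probability_sets_no_fruit(self):
        trials = simulate_crossings(small_config())
        control = trials[trials["treatment"] == "control"]
        assert (control["fruit"] == 0).all()
        seed_cols = ["n_large", "n_small", "n_aborted", "n_empty"]
        assert (control[seed_cols].sum(axis=1) == 0).all()

    def test_high_dispersion_limit_is_poisson_like(self):
        cell = CrossingCellConfig(1.0, 100.0, 1e6, (0.7, 0.1, 0.1, 0.1))
        cfg = small_config(crossing={("white", "intraform"): cell,
                                     ("white", "interform"): cell,
                                     ("pink", "intraform"): cell,
                                     ("pink", "interform"): cell},
                           n_per_cell=4000, seed=2)
        trials = simulate_crossings(cfg)
        tubes = trials["pollen_tubes"].to_numpy()
        assert tubes.var() == pytest.approx(tubes.mean(), rel=0.1)

    def test_invalid_embryo_simplex_rejected(self):
        with pytest.raises(InvalidInputError):
            CrossingCellConfig(0.5, 10.0, 1.0, (0.5, 0.5, 0.5, 0.5))


class TestSpectra:
    def test_zero_noise_identical_params_zero_distance(self):
        sc = SpectrumConfig(base=0.6, bands=((500.0, 40.0, -0.3),), noise_sd=0.0)
        cfg = small_config(spectra={"a": sc, "b": sc}, n_spectra_per_form=1)
        spectra = simulate_spectra(cfg)
        model = VisionModel.honeybee()
        d = chromatic_distance(locus_of(spectra["a"][0], model),
                               locus_of(spectra["b"][0], model))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_noise_produces_small_positive_spread(self):
        cfg = small_config(n_spectra_per_form=8)
        spectra = simulate_spectra(cfg)
        model = VisionModel.honeybee()
        white = [locus_of(s, model) for s in spectra["white"]]
        pink = [locus_of(s, model) for s in spectra["pink"]]
        dists = [chromatic_distance(w, p) for w in white for p in pink]
        assert np.std(dists) > 0
        assert np.std(dists) < 0.05  # noise SD 0.005 barely moves loci

    def test_values_clipped_to_physical_range(self):
        sc = SpectrumConfig(base=1.2, bands=(), noise_sd=0.1)
        cfg = small_config(spectra={"x": sc}, n_spectra_per_form=2)
        spectra = simulate_spectra(cfg)
        for s in spectra["x"]:
            assert s.values.min() >= 0.0 and s.values.max() <= 1.0


def test_expected_relative_success_closed_form():
    assert expected_relative_success(1.0) == 0.0
    assert expected_relative_success(0.0) == 1.0
    # equal availability reduces to (1-k)/(1+k)
    assert expected_relative_success(0.9) == pytest.approx(1 / 19)
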