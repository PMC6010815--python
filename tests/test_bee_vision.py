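"""Colour-hexagon vision model: catches, loci, distances, discrimination."""

import math

import numpy as np
import pytest

from isobarrier.bee_vision import (CANONICAL_GRID, HexLocus, Spectrum,
                                   VisionModel, chromatic_distance,
                                   daylight_illuminant, discriminable,
                                   excitation, green_foliage_background,
                                   hexagon_locus, locus_of, pigment_template,
                                   quantum_catch, resample)
from isobarrier.errors import InvalidInputError


@pytest.fixture(scope="module")
def model():
    return VisionModel.honeybee()


def flat(value, kind="reflectance", name="flat"):
    return Spectrum(CANONICAL_GRID, np.full(CANONICAL_GRID.size, value),
                    kind=kind, name=name)


class TestResample:
    def test_identity_on_canonical_grid(self):
        s = flat(0.5)
        out = resample(s)
        assert np.array_equal(out.values, s.values)

    def test_fine_grid_constant_preserved(self):
        wl = np.arange(300.0, 700.37, 0.37)
        s = Spectrum(wl, np.full(wl.size, 0.3))
        out = resample(s)
        assert np.allclose(out.values, 0.3)
        assert np.array_equal(out.wavelengths, CANONICAL_GRID)

    def test_linear_ramp_preserved_at_grid_points(self):
        wl = np.array([300.0, 700.0])
        s = Spectrum(wl, np.array([0.0, 1.0]))
        out = resample(s)
        assert np.allclose(out.values, (CANONICAL_GRID - 300.0) / 400.0)

    def test_extrapolation_refused(self):
        s = Spectrum(np.array([350.0, 700.0]), np.array([0.1, 0.2]))
        with pytest.raises(InvalidInputError):
            resample(s)

    def test_negative_values_clipped(self, caplog):
        wl = np.array([300.0, 700.0])
        s = Spectrum(wl, np.array([-0.1, 0.2]))
        with caplog.at_level("WARNING"):
            out = resample(s)
        assert out.values.min() == 0.0


class TestTemplate:
    @pytest.mark.parametrize("lmax", [340.0, 436.0, 544.0])
    def test_alpha_band_peaks_at_lambda_max_with_unit_height(self, lmax):
        s = pigment_template(lmax, beta_band=False)
        assert s.values.max() == pytest.approx(1.0)
        peak = s.wavelengths[np.argmax(s.values)]
        assert abs(peak - lmax) <= 1.0  # within one grid step

    @pytest.mark.parametrize("lmax", [340.0, 436.0, 544.0])
    def test_full_template_near_unity_at_lambda_max(self, lmax):
        # the beta band can nudge a UV pigment's maximum a few nm shortward
        s = pigment_template(lmax)
        assert s.values.max() == pytest.approx(1.0)
        idx = int(np.argmin(np.abs(s.wavelengths - lmax)))
        assert s.values[idx] >= 0.98

    def test_alpha_band_half_maximum_width(self):
        # without the beta band the curve is unimodal; its full width at
        # half maximum for a mid-wavelength pigment is a few tens of nm
        s = pigment_template(544.0, beta_band=False)
        above = s.wavelengths[s.values >= 0.5]
        fwhm = above[-1] - above[0]
        assert 60 <= fwhm <= 120

    def test_out_of_range_peak_rejected(self):
        with pytest.raises(InvalidInputError):
            pigment_template(250.0)


class TestQuantumCatch:
    def test_background_catches_are_unity(self, model):
        p = quantum_catch(model.background, model)
        assert p == pytest.approx((1.0, 1.0, 1.0))

    def test_doubled_background_doubles_catches(self, model):
        stim = Spectrum(model.background.wavelengths,
                        2.0 * model.background.values)
        assert quantum_catch(stim, model) == pytest.approx((2.0, 2.0, 2.0))

    def test_illuminant_rescaling_cancels(self, model):
        bright = VisionModel.honeybee(illuminant=Spectrum(
            CANONICAL_GRID, 7.0 * daylight_illuminant().values,
            kind="illuminant"))
        stim = flat(0.4)
        assert quantum_catch(stim, bright) == pytest.approx(
            quantum_catch(stim, model))


def test_excitation_transduction():
    assert excitation(0.0) == 0.0
    assert excitation(1.0) == 0.5
    assert excitation(1e9) == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(InvalidInputError):
        excitation(-0.1)


class TestHexagonLocus:
    def test_adapted_background_at_origin(self):
        assert hexagon_locus(0.5, 0.5, 0.5).xy == pytest.approx((0.0, 0.0))

    def test_pure_blue_vertex(self):
        assert hexagon_locus(0.0, 1.0, 0.0).xy == pytest.approx((0.0, 1.0))

    def test_pure_green_vertex(self):
        assert hexagon_locus(0.0, 0.0, 1.0).xy == pytest.approx(
            (math.sqrt(3) / 2, -0.5))

    def test_excitations_validated(self):
        with pytest.raises(InvalidInputError):
            hexagon_locus(1.5, 0.0, 0.0)


class TestChromaticDistance:
    def test_identical_loci(self):
        a = hexagon_locus(0.3, 0.4, 0.5)
        assert chromatic_distance(a, a) == 0.0

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = (hexagon_locus(*rng.uniform(0, 1, 3)) for _ in range(3))
            assert chromatic_distance(a, b) == pytest.approx(chromatic_distance(b, a))
            assert (chromatic_distance(a, c)
                    <= chromatic_distance(a, b) + chromatic_distance(b, c) + 1e-12)


class TestModelInvariants:
    def test_background_and_its_multiples_map_to_origin(self, model):
        for k in (1.0, 0.25, 3.0):
            stim = Spectrum(model.background.wavelengths,
                            k * model.background.values)
            locus = locus_of(stim, model)
            assert locus.xy == pytest.approx((0.0, 0.0), abs=1e-12)

    @pytest.mark.parametrize("k", [0.2, 3.0, 50.0])
    def test_von_kries_joint_rescaling_invariance(self, model, k):
        """Uniformly rescaling stimulus and background together (an overall
        intensity change) leaves the locus unchanged — the background
        normalisation discounts it exactly."""
        stim = flat(0.4)
        scaled_model = VisionModel.honeybee(background=Spectrum(
            CANONICAL_GRID, k * model.background.values, kind="background"))
        scaled_stim = Spectrum(CANONICAL_GRID, k * stim.values)
        a = locus_of(stim, model)
        b = locus_of(scaled_stim, scaled_model)
        assert b.xy == pytest.approx(a.xy, abs=1e-9)

    def test_spectral_illuminant_shift_only_weakly_moves_loci(self, model):
        """A wavelength-dependent illumination change (a spectral tilt of
        +/-40%) is compensated only approximately by chromatic adaptation;
        the residual locus shift stays small."""
        stim = flat(0.4)
        tilt = 0.6 + 0.8 * (CANONICAL_GRID - 300.0) / 400.0
        tilted_model = VisionModel.honeybee(illuminant=Spectrum(
            CANONICAL_GRID, tilt * model.illuminant.values, kind="illuminant"))
        a = locus_of(stim, model)
        b = locus_of(stim, tilted_model)
        assert chromatic_distance(a, b) < 0.05

    def test_loci_bounded_by_hexagon(self, model, rng):
        for _ in range(20):
            stim = Spectrum(CANONICAL_GRID, rng.uniform(0, 1.2, CANONICAL_GRID.size))
            locus = locus_of(stim, model)
            assert abs(locus.x) <= math.sqrt(3) / 2 + 1e-12
            assert abs(locus.y) <= 1.0 + 1e-12

    def test_green_band_reflectance_pulls_locus_to_positive_x(self, model):
        base = flat(0.2)
        boosted_vals = base.values + 0.5 * np.exp(
            -(((CANONICAL_GRID - 544.0) / 25.0) ** 2))
        boosted = Spectrum(CANONICAL_GRID, boosted_vals)
        assert locus_of(boosted, model).x > locus_of(base, model).x


def test_discriminable_threshold():
    assert discriminable(0.21)[0] is True
    assert discriminable(0.06)[0] is False
    assert discriminable(0.0, 0.01)[0] is False
    flag, margin = discriminable(0.15, 0.1)
    assert flag and margin == pytest.approx(0.05)


def test_default_scene_spectra_are_physical():
    illum = daylight_illuminant()
    bg = green_foliage_background()
    assert illum.values.min() > 0
    assert 0 < bg.values.min() and bg.values.max() < 1
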