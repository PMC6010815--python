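"""Colour-hexagon model of trichromatic hymenopteran vision.

The hexagon model maps a reflectance spectrum viewed against an adapting
background into a two-dimensional chromaticity plane:

1. quantum catch per receptor ``i`` (UV, blue, green)::

       P_i = int stimulus(l) * illuminant(l) * S_i(l) dl
             ------------------------------------------   (von Kries)
             int background(l) * illuminant(l) * S_i(l) dl

2. nonlinear transduction to excitation ``E_i = P_i / (P_i + 1)``
   (half-maximal response at the adapting background);
3. hexagon coordinates ``x = (sqrt(3)/2) * (E_g - E_uv)``,
   ``y = E_b - (E_uv + E_g)/2``.

The adapting background itself lands at the origin, and loci are bounded
by the unit hexagon (|x| <= sqrt(3)/2, |y| <= 1).  Chromatic contrast is
Euclidean distance in the plane, in "hexagon units"; a pair of colours is
taken as bee-discriminable when the distance exceeds a just-noticeable-
difference threshold (0.1 hexagon units by default, configurable).

All spectra are resampled to a canonical 1-nm grid on 300–700 nm and
integrated by the trapezoid rule.  Receptor sensitivities default to
A1-pigment nomogram templates (alpha plus beta band) at documented peak
wavelengths for honeybee- and bumblebee-like vision; measured sensitivity
tables can be supplied instead and the choice is recorded in output
metadata.  The default illuminant is an idealized open-sky daylight
(normalised 6500 K black-body photon flux) and the default adapting
background a parametric green-foliage reflectance; both are overridable
by any spectrum loaded from file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_GRID",
    "Spectrum",
    "VisionModel",
    "HexLocus",
    "resample",
    "pigment_template",
    "daylight_illuminant",
    "green_foliage_background",
    "quantum_catch",
    "excitation",
    "hexagon_locus",
    "locus_of",
    "chromatic_distance",
    "discriminable",
]

#: Canonical wavelength grid: 1-nm steps over the bee-visual range.
CANONICAL_GRID: np.ndarray = np.arange(300.0, 701.0, 1.0)

_KIND = ("reflectance", "illuminant", "sensitivity", "background")


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral curve on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.shape != vals.shape or wl.size < 2:
            raise InvalidInputError("spectrum needs matching 1-D wavelength/value arrays")
        if np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(vals)):
            raise InvalidInputError("spectrum contains non-finite values")
        if self.kind not in _KIND:
            raise InvalidInputError(f"kind must be one of {_KIND}, got {self.kind!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)


def resample(spectrum: Spectrum, grid: np.ndarray | None = None) -> Spectrum:
    """Linear interpolation of a spectrum onto a target grid (no extrapolation).

    Negative interpolated values are clipped to 0 with a warning; the
    input must cover the full requested grid.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    wl = spectrum.wavelengths
    if grid[0] < wl[0] or grid[-1] > wl[-1]:
        raise InvalidInputError(
            f"spectrum {spectrum.name!r} covers [{wl[0]}, {wl[-1]}] nm but the "
            f"grid requires [{grid[0]}, {grid[-1]}] nm; refusing to extrapolate"
        )
    vals = np.interp(grid, wl, spectrum.values)
    if np.any(vals < 0):
        logger.warning("clipping %d negative values in %r to 0",
                       int((vals < 0).sum()), spectrum.name)
        vals = np.clip(vals, 0.0, None)
    return Spectrum(grid, vals, kind=spectrum.kind, name=spectrum.name)


def pigment_template(lambda_max: float, grid: np.ndarray | None = None,
                     beta_band: bool = True) -> Spectrum:
    """A1-pigment nomogram sensitivity template peaking at ``lambda_max``.

    Smooth unimodal alpha band plus (optionally) the secondary beta band,
    normalised to a maximum of 1.  Valid for peaks within 300–700 nm.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise InvalidInputError(f"lambda_max {lambda_max} nm outside 300-700 nm")
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x)) + 0.674
    )
    sens = alpha
    if beta_band:
        lmb = 189.0 + 0.315 * lambda_max
        bwb = -40.5 + 0.195 * lambda_max
        sens = alpha + 0.26 * np.exp(-(((grid - lmb) / bwb) ** 2))
    sens = sens / sens.max()
    return Spectrum(grid, sens, kind="sensitivity", name=f"template_{lambda_max:.0f}nm")


def daylight_illuminant(grid: np.ndarray | None = None,
                        temperature_k: float = 6500.0) -> Spectrum:
    """Idealized open-sky daylight: normalised black-body photon flux.

    A smooth stand-in for measured daylight tables; adequate because the
    von Kries step cancels overall illuminant scale and the analyses here
    are contrast-based.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    h, c, kb = 6.626e-34, 2.998e8, 1.381e-23
    lam = grid * 1e-9
    # spectral photon radiance ~ (1/lam^4) / (exp(hc/lam k T) - 1)
    photons = 1.0 / (lam ** 4 * (np.exp(h * c / (lam * kb * temperature_k)) - 1.0))
    photons = photons / photons.max()
    return Spectrum(grid, photons, kind="illuminant", name=f"daylight_{temperature_k:.0f}K")


def green_foliage_background(grid: np.ndarray | None = None) -> Spectrum:
    """Parametric green-leaf reflectance: low UV/blue, green bump, red edge.

    Synthetic curve standing in for a measured foliage spectrum as the
    chromatic adapting background.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    base = 0.06
    green_bump = 0.14 * np.exp(-(((grid - 550.0) / 40.0) ** 2))
    red_edge = 0.35 / (1.0 + np.exp(-(grid - 705.0) / 12.0))
    vals = base + green_bump + red_edge
    return Spectrum(grid, vals, kind="background", name="green_foliage_synthetic")


@dataclass(frozen=True)
class VisionModel:
    """Receptor sensitivities plus illuminant and adapting background."""

    uv: Spectrum
    blue: Spectrum
    green: Spectrum
    illuminant: Spectrum = field(default_factory=daylight_illuminant)
    background: Spectrum = field(default_factory=green_foliage_background)
    name: str = "custom"

    def __post_init__(self) -> None:
        for s in (self.uv, self.blue, self.green):
            if np.any(s.values < 0):
                raise InvalidInputError("receptor sensitivities must be nonnegative")
        object.__setattr__(self, "uv", resample(self.uv))
        object.__setattr__(self, "blue", resample(self.blue))
        object.__setattr__(self, "green", resample(self.green))
        object.__setattr__(self, "illuminant", resample(self.illuminant))
        object.__setattr__(self, "background", resample(self.background))

    @classmethod
    def honeybee(cls, **overrides) -> "VisionModel":
        """Honeybee-like trichromat: template peaks at 344/436/544 nm."""
        return cls(uv=pigment_template(344.0), blue=pigment_template(436.0),
                   green=pigment_template(544.0), name="honeybee", **overrides)

    @classmethod
    def bumblebee(cls, **overrides) -> "VisionModel":
        """Bumblebee-like trichromat: template peaks at 347/436/543 nm."""
        return cls(uv=pigment_template(347.0), blue=pigment_template(436.0),
                   green=pigment_template(543.0), name="bumblebee", **overrides)

    def metadata(self) -> dict:
        return {
            "model": self.name,
            "receptors": {"uv": self.uv.name, "blue": self.blue.name,
                          "green": self.green.name},
            "illuminant": self.illuminant.name,
            "background": self.background.name,
        }


def _catch(stimulus_vals: np.ndarray, model: VisionModel, sens: Spectrum) -> float:
    integrand = stimulus_vals * model.illuminant.values * sens.values
    return float(np.trapezoid(integrand, CANONICAL_GRID))


def quantum_catch(stimulus: Spectrum, model: VisionModel) -> tuple[float, float, float]:
    """Background-normalised (von Kries) quantum catches (P_uv, P_b, P_g)."""
    stim = resample(stimulus)
    catches = []
    for sens in (model.uv, model.blue, model.green):
        denom = _catch(model.background.values, model, sens)
        if denom <= 0:
            raise InvalidInputError(
                f"background catch is zero for receptor {sens.name!r}"
            )
        catches.append(_catch(stim.values, model, sens) / denom)
    return tuple(catches)


def excitation(p: float) -> float:
    """Receptor excitation ``E = P/(P+1)`` in [0, 1)."""
    if p < 0:
        raise InvalidInputError("quantum catch must be nonnegative")
    return p / (p + 1.0)


@dataclass(frozen=True)
class HexLocus:
    """A stimulus' position in the colour hexagon."""

    e_uv: float
    e_b: float
    e_g: float

    @property
    def x(self) -> float:
        return (math.sqrt(3.0) / 2.0) * (self.e_g - self.e_uv)

    @property
    def y(self) -> float:
        return self.e_b - (self.e_uv + self.e_g) / 2.0

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


def hexagon_locus(e_uv: float, e_b: float, e_g: float) -> HexLocus:
    """Hexagon coordinates from the three receptor excitations."""
    for e in (e_uv, e_b, e_g):
        if not 0.0 <= e <= 1.0:
            raise InvalidInputError(f"excitations must lie in [0, 1], got {e}")
    return HexLocus(e_uv, e_b, e_g)


def locus_of(stimulus: Spectrum, model: VisionModel) -> HexLocus:
    """Full pipeline: spectrum -> catches -> excitations -> hexagon locus."""
    p_uv, p_b, p_g = quantum_catch(stimulus, model)
    return hexagon_locus(excitation(p_uv), excitation(p_b), excitation(p_g))


def chromatic_distance(a: HexLocus, b: HexLocus) -> float:
    """Euclidean chromatic contrast between two loci, in hexagon units."""
    return math.hypot(a.x - b.x, a.y - b.y)


def discriminable(distance: float, threshold: float = 0.1) -> tuple[bool, float]:
    """Whether a chromatic distance exceeds the JND threshold, and by how much.

    Returns ``(distance > threshold, distance - threshold)``.
    """
    if distance < 0:
        raise InvalidInputError("distance must be nonnegative")
    return distance > threshold, distance - threshold
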