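"""Synthetic field data with the statistical structure the analyses assume.

The generator emulates a two-colour-form pollination study: overlapping
multi-week flowering seasons, foragers whose form-to-form movement is a
two-state Markov chain with a per-species constancy parameter, a
hand-pollination crossing design with binary fruit set, overdispersed
pollen-tube counts and four-category embryo composition, and smooth
parametric floral reflectance spectra (white-like, pink-like and an
intermediate blend).

Every generator draws from a ``numpy.random.Generator`` and is
deterministic under a fixed seed.  The per-species stay-probability
``kappa`` links directly to the pollinator barrier: with two equally
available forms, the expected relative heterospecific success is
``h = (1-kappa)/(1+kappa)``, which makes full-pipeline parameter-recovery
checks possible in closed form.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barrier_metrics import FloweringInterval
from .bee_vision import CANONICAL_GRID, Spectrum
from .constancy import ForagingBout
from .errors import InvalidInputError

__all__ = [
    "SpeciesConfig",
    "CrossingCellConfig",
    "SpectrumConfig",
    "SimulationConfig",
    "simulate_phenology",
    "simulate_foraging",
    "simulate_crossings",
    "simulate_spectra",
    "expected_relative_success",
    "simulate_study",
]

TREATMENTS = ("self", "intraform", "interform", "control")
EMBRYO_CATEGORIES = ("large", "small", "aborted", "empty")


@dataclass(frozen=True)
class SpeciesConfig:
    """One forager species: constancy parameter and sampling effort."""

    name: str
    kappa: float  # probability of staying on the current form per move
    n_foragers: int
    mean_bout_length: float  # mean visits per bout (>= 2 enforced at draw)
    n_bouts_per_forager: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise InvalidInputError(f"kappa must be in [0,1], got {self.kappa}")
        if self.n_foragers < 1 or self.n_bouts_per_forager < 1:
            raise InvalidInputError("forager/bout counts must be positive")


@dataclass(frozen=True)
class CrossingCellConfig:
    """One maternal form x treatment cell of the crossing design."""

    fruit_prob: float  # Bernoulli fruit-set probability
    tube_mean: float  # mean pollen tubes entering the ovary
    tube_dispersion: float  # negative-binomial k; larger -> closer to Poisson
    embryo_probs: tuple[float, float, float, float]  # large/small/aborted/empty

    def __post_init__(self) -> None:
        if not 0.0 <= self.fruit_prob <= 1.0:
            raise InvalidInputError("fruit_prob must be a probability")
        if self.tube_mean < 0 or self.tube_dispersion <= 0:
            raise InvalidInputError("tube_mean >= 0 and tube_dispersion > 0 required")
        p = np.asarray(self.embryo_probs, dtype=float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("embryo_probs must be a 4-simplex")


@dataclass(frozen=True)
class SpectrumConfig:
    """Parametric floral reflectance: base + Gaussian bands + sigmoid edges + noise.

    ``bands`` are Gaussian bumps/dips (centre nm, width nm, amplitude);
    ``edges`` are logistic steps (centre nm, width nm, amplitude) — the
    natural shape for petal reflectance edges (a white petal's UV cut-on,
    a magenta petal's red edge).
    """

    base: float
    bands: tuple[tuple[float, float, float], ...] = ()
    edges: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.005


def _default_species() -> tuple[SpeciesConfig, ...]:
    # an apid-like highly constant species and a less constant bumblebee-like one
    return (
        SpeciesConfig("apis_like", kappa=0.95, n_foragers=30,
                      mean_bout_length=10.0),
        SpeciesConfig("bombus_like", kappa=0.80, n_foragers=26,
                      mean_bout_length=10.0),
    )


def _default_crossing() -> dict[tuple[str, str], CrossingCellConfig]:
    cells: dict[tuple[str, str], CrossingCellConfig] = {}
    # white maternal: strong post-pollination penalties on interform crosses
    cells[("white", "self")] = CrossingCellConfig(0.85, 146.0, 1.5, (0.72, 0.12, 0.08, 0.08))
    cells[("white", "intraform")] = CrossingCellConfig(0.85, 119.0, 1.5, (0.72, 0.12, 0.08, 0.08))
    cells[("white", "interform")] = CrossingCellConfig(0.37, 126.0, 1.5, (0.46, 0.22, 0.16, 0.16))
    cells[("white", "control")] = CrossingCellConfig(0.0, 0.0, 1.5, (0.0, 0.0, 0.0, 1.0))
    # pink maternal: weak post-pollination barriers
    cells[("pink", "self")] = CrossingCellConfig(0.75, 42.0, 1.5, (0.51, 0.19, 0.15, 0.15))
    cells[("pink", "intraform")] = CrossingCellConfig(0.75, 84.0, 1.5, (0.65, 0.15, 0.10, 0.10))
    cells[("pink", "interform")] = CrossingCellConfig(0.67, 70.0, 1.5, (0.63, 0.15, 0.11, 0.11))
    cells[("pink", "control")] = CrossingCellConfig(0.0, 0.0, 1.5, (0.0, 0.0, 0.0, 1.0))
    return cells


def _default_spectra() -> dict[str, SpectrumConfig]:
    return {
        # white-like: bright above a ~408-nm cut-on, UV-dark (typical white petal)
        "white": SpectrumConfig(base=0.05, edges=((408.0, 10.0, 0.70),)),
        # pink/magenta-like: dark through the bee-visual range except a weak
        # blue reflection, with a steep red edge at ~600 nm
        "pink": SpectrumConfig(base=0.06, edges=((600.0, 18.0, 0.60),),
                               bands=((440.0, 45.0, 0.06),)),
        # intermediate: white-like with a shallow pink (green-absorbing) dip
        "intermediate": SpectrumConfig(base=0.05, edges=((408.0, 10.0, 0.64),),
                                       bands=((530.0, 55.0, -0.10),)),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full study configuration; defaults emulate the field conditions.

    Two forms co-flowering for most of a roughly seven-week season, two
    bee species differing in constancy foraging over an equal 20:20 array
    of potted plants, a four-treatment crossing design, and white/pink/
    intermediate-like reflectance spectra.
    """

    seed: int = 0
    forms: tuple[str, str] = ("white", "pink")
    n_plants: dict = field(default_factory=lambda: {"white": 77, "pink": 40})
    # window of per-plant first-flower dates per form
    season_windows: dict = field(default_factory=lambda: {
        "white": (datetime.date(2016, 7, 24), datetime.date(2016, 8, 31)),
        "pink": (datetime.date(2016, 7, 31), datetime.date(2016, 9, 5)),
    })
    flower_lifespan_days: float = 10.0
    lifespan_sd_days: float = 2.0
    species: tuple[SpeciesConfig, ...] = field(default_factory=_default_species)
    availability: dict = field(default_factory=lambda: {"white": 20, "pink": 20})
    n_per_cell: int = 30
    crossing: dict = field(default_factory=_default_crossing)
    seeds_per_fruit: int = 300
    spectra: dict = field(default_factory=_default_spectra)
    n_spectra_per_form: int = 5

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build a config from a YAML-style mapping (see data/default_scenario.yaml)."""
        kwargs: dict = {}
        for key in ("seed", "n_plants", "flower_lifespan_days", "lifespan_sd_days",
                    "availability", "n_per_cell", "seeds_per_fruit",
                    "n_spectra_per_form"):
            if key in raw:
                kwargs[key] = raw[key]
        if "forms" in raw:
            kwargs["forms"] = tuple(raw["forms"])
        if "season_windows" in raw:
            kwargs["season_windows"] = {
                form: (_as_date(lo), _as_date(hi))
                for form, (lo, hi) in raw["season_windows"].items()
            }
        if "species" in raw:
            kwargs["species"] = tuple(SpeciesConfig(**sp) for sp in raw["species"])
        if "crossing" in raw:
            kwargs["crossing"] = {
                (form, treatment): CrossingCellConfig(
                    fruit_prob=cell["fruit_prob"], tube_mean=cell["tube_mean"],
                    tube_dispersion=cell["tube_dispersion"],
                    embryo_probs=tuple(cell["embryo_probs"]))
                for form, cells in raw["crossing"].items()
                for treatment, cell in cells.items()
            }
        if "spectra" in raw:
            kwargs["spectra"] = {
                form: SpectrumConfig(
                    base=sc["base"],
                    bands=tuple(tuple(b) for b in sc.get("bands", ())),
                    edges=tuple(tuple(e) for e in sc.get("edges", ())),
                    noise_sd=sc.get("noise_sd", 0.005))
                for form, sc in raw["spectra"].items()
            }
        return cls(**kwargs)


def _as_date(value) -> datetime.date:
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


def simulate_phenology(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, FloweringInterval], pd.DataFrame]:
    """Per-plant flowering schedules and the resulting form-level intervals.

    Each plant's first-flower day is uniform within its form's window;
    its scape flowers for a normally distributed span around the mean
    flower lifespan (floored at 1 day).  The form-level interval is the
    union (min first day, max last day) over its plants.
    """
    rng = config.rng() if rng is None else rng
    rows = []
    intervals: dict[str, FloweringInterval] = {}
    for form in config.forms:
        start, end = config.season_windows[form]
        if end < start:
            raise InvalidInputError(f"empty season window for {form!r}")
        n = config.n_plants[form]
        offsets = rng.integers(0, (end - start).days + 1, size=n)
        spans = np.maximum(
            np.rint(rng.normal(config.flower_lifespan_days,
                               config.lifespan_sd_days, size=n)).astype(int), 1)
        firsts = [start + datetime.timedelta(days=int(o)) for o in offsets]
        lasts = [f + datetime.timedelta(days=int(s) - 1) for f, s in zip(firsts, spans)]
        for i, (f, l) in enumerate(zip(firsts, lasts)):
            rows.append({"form": form, "plant_id": f"{form}_{i:03d}",
                         "first_day": f, "last_day": l})
        intervals[form] = FloweringInterval(form, min(firsts), max(lasts))
    return intervals, pd.DataFrame(rows)


def expected_relative_success(kappa: float, availability: float = 0.5) -> float:
    """Closed-form pollinator-stage ``h = H/C`` implied by the Markov forager.

    With stay-probability ``kappa`` and focal-form availability ``a``,
    the chain's stationary occupancy equals availability, so expected
    same-form arrivals at the focal form accrue at rate
    ``a * (kappa + (1-kappa)*a)`` and cross-form arrivals at
    ``(1-a) * (1-kappa) * a``; the ratio is
    ``(1-a)(1-kappa) / (kappa + (1-kappa)*a)``, which reduces to
    ``(1-kappa)/(1+kappa)`` at equal availability.
    """
    if not 0.0 <= kappa <= 1.0 or not 0.0 < availability < 1.0:
        raise InvalidInputError("kappa in [0,1] and availability in (0,1) required")
    return ((1.0 - availability) * (1.0 - kappa)
            / (kappa + (1.0 - kappa) * availability))


def simulate_foraging(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[ForagingBout]:
    """Markov-chain foraging bouts over the two-form plant array.

    Each move stays on the current form with probability ``kappa`` and
    otherwise chooses a form by availability (so a "switch" draw can still
    land on the same form).  Successive visits always go to a different
    plant.  Bout lengths are Poisson around the species mean, floored at 2.
    """
    rng = config.rng() if rng is None else rng
    forms = config.forms
    avail = np.array([config.availability[f] for f in forms], dtype=float)
    avail = avail / avail.sum()
    bouts: list[ForagingBout] = []
    for sp in config.species:
        for i in range(sp.n_foragers):
            fid = f"{sp.name}_{i:03d}"
            for b in range(sp.n_bouts_per_forager):
                length = max(int(rng.poisson(sp.mean_bout_length)), 2)
                form_idx = int(rng.choice(2, p=avail))
                visits = []
                prev_plant = -1
                for _ in range(length):
                    n_avail = config.availability[forms[form_idx]]
                    plant = int(rng.integers(0, n_avail))
                    if plant == prev_plant:  # move to a different plant
                        plant = (plant + 1) % n_avail
                    visits.append((f"{forms[form_idx]}_{plant:02d}", forms[form_idx]))
                    prev_plant = plant
                    if rng.random() >= sp.kappa:
                        new_idx = int(rng.choice(2, p=avail))
                        if new_idx != form_idx:
                            prev_plant = -1
                        form_idx = new_idx
                bouts.append(ForagingBout(fid, sp.name, tuple(visits)))
    return bouts


def simulate_crossings(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Hand-pollination trial table: one row per treated flower.

    Columns: maternal_form, treatment, replicate, fruit (0/1),
    pollen_tubes (negative-binomial count), and per-category embryo counts
    among ~300 scored seeds (zeros when no fruit formed).
    """
    rng = config.rng() if rng is None else rng
    rows = []
    for (form, treatment), cell in config.crossing.items():
        n = config.n_per_cell
        fruit = rng.binomial(1, cell.fruit_prob, size=n)
        if cell.tube_mean > 0:
            k = cell.tube_dispersion
            tubes = rng.negative_binomial(k, k / (k + cell.tube_mean), size=n)
        else:
            tubes = np.zeros(n, dtype=int)
        embryos = rng.multinomial(config.seeds_per_fruit,
                                  np.asarray(cell.embryo_probs), size=n)
        embryos = embryos * fruit[:, None]  # no seeds without a fruit
        for i in range(n):
            row = {"maternal_form": form, "treatment": treatment, "replicate": i,
                   "fruit": int(fruit[i]), "pollen_tubes": int(tubes[i])}
            row.update({f"n_{cat}": int(embryos[i, j])
                        for j, cat in enumerate(EMBRYO_CATEGORIES)})
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_spectra(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, list[Spectrum]]:
    """Replicate reflectance spectra per form: parametric curve + noise."""
    rng = config.rng() if rng is None else rng
    grid = CANONICAL_GRID
    out: dict[str, list[Spectrum]] = {}
    for form, sc in config.spectra.items():
        curves = []
        for i in range(config.n_spectra_per_form):
            vals = np.full_like(grid, sc.base)
            for centre, width, amp in sc.bands:
                vals = vals + amp * np.exp(-(((grid - centre) / width) ** 2))
            for centre, width, amp in sc.edges:
                vals = vals + amp / (1.0 + np.exp(-(grid - centre) / width))
            vals = vals + rng.normal(0.0, sc.noise_sd, size=grid.size)
            vals = np.clip(vals, 0.0, 1.0)
            curves.append(Spectrum(grid, vals, kind="reflectance",
                                   name=f"{form}_{i:02d}"))
        out[form] = curves
    return out


def simulate_study(config: SimulationConfig) -> dict:
    """Generate every input a full analysis needs, from one seed.

    Returns a dict with keys ``intervals``, ``schedules``, ``bouts``,
    ``crossings`` and ``spectra``.  Deterministic under ``config.seed``:
    the four generators consume one shared random stream in a fixed order.
    """
    rng = config.rng()
    intervals, schedules = simulate_phenology(config, rng)
    bouts = simulate_foraging(config, rng)
    crossings = simulate_crossings(config, rng)
    spectra = simulate_spectra(config, rng)
    return {"intervals": intervals, "schedules": schedules, "bouts": bouts,
            "crossings": crossings, "spectra": spectra}
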