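"""Closed-form reproductive-isolation (RI) indices for single barriers.

Two index families are used in the plant reproductive-isolation literature
and both appear here:

* phenology:  ``RI = 1 - S/(S+U)`` where ``S`` is the co-flowering
  (shared) time of the two taxa and ``U`` the focal taxon's unshared
  flowering time.  The index lives in [0, 1].
* paired success:  ``RI = 1 - 2*H/(H+C)`` where ``C`` is the conspecific
  (intraform) and ``H`` the heterospecific (interform) success measure for
  one maternal direction.  The index lives in [-1, 1]; negative values mean
  heterospecific crosses outperform conspecific ones.

Both formulas are ratio-only, so ``C`` and ``H`` may be raw counts, means
or proportions — as long as the two members of one pair are measured in
the same units.  The :class:`SuccessPair` record keeps a co-measured pair
together with its maternal direction and barrier name.

Directional asymmetry of a barrier is the absolute difference of its RI in
the two maternal directions.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedRIError

logger = logging.getLogger(__name__)

__all__ = [
    "FloweringInterval",
    "SuccessPair",
    "BarrierEstimate",
    "overlap_days",
    "phenology_ri",
    "pairwise_ri",
    "asymmetry",
    "bootstrap_ci",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed field tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FloweringInterval:
    """One colour form's flowering season, inclusive of both endpoint days."""

    form: str
    first_day: datetime.date
    last_day: datetime.date

    def __post_init__(self) -> None:
        if self.first_day > self.last_day:
            raise InvalidInputError(
                f"reversed flowering interval for {self.form!r}: "
                f"{self.first_day} > {self.last_day}"
            )

    @property
    def duration(self) -> int:
        """Inclusive day count of the interval (a one-day season has duration 1)."""
        return (self.last_day - self.first_day).days + 1


@dataclass(frozen=True)
class SuccessPair:
    """Co-measured conspecific/heterospecific success for one maternal direction.

    ``conspecific`` (C) and ``heterospecific`` (H) must share units within
    the pair; the RI formula cancels the units.  ``n`` optionally records
    the sample size behind the pair.
    """

    conspecific: float
    heterospecific: float
    maternal_form: str = ""
    barrier: str = ""
    n: int | None = None

    def __post_init__(self) -> None:
        if self.conspecific < 0 or self.heterospecific < 0:
            raise InvalidInputError(
                f"success measures must be nonnegative, got C={self.conspecific}, "
                f"H={self.heterospecific} ({self.barrier}/{self.maternal_form})"
            )
        if self.conspecific == 0 and self.heterospecific == 0:
            raise UndefinedRIError(
                f"C = H = 0 for barrier {self.barrier!r}, maternal form "
                f"{self.maternal_form!r}: RI is undefined with no observed events"
            )


@dataclass(frozen=True)
class BarrierEstimate:
    """A single barrier's RI in one maternal direction, with optional CI."""

    barrier: str
    maternal_form: str
    ri: float
    conspecific: float
    heterospecific: float
    n: int | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @classmethod
    def from_pair(cls, pair: SuccessPair, **kwargs) -> "BarrierEstimate":
        return cls(
            barrier=pair.barrier,
            maternal_form=pair.maternal_form,
            ri=pairwise_ri(pair),
            conspecific=pair.conspecific,
            heterospecific=pair.heterospecific,
            n=pair.n,
            **kwargs,
        )

    def with_ci(self, low: float, high: float) -> "BarrierEstimate":
        return dataclasses.replace(self, ci_low=low, ci_high=high)


def overlap_days(a: FloweringInterval, b: FloweringInterval) -> tuple[int, int]:
    """Shared and unshared flowering days of ``a`` against ``b``.

    Day counting is inclusive of both the first and the last flowering day,
    so two identical one-day seasons share 1 day.  Returns
    ``(shared_days, unshared_days_of_a)``; disjoint seasons share 0 days.
    """
    start = max(a.first_day, b.first_day)
    end = min(a.last_day, b.last_day)
    shared = max((end - start).days + 1, 0)
    return shared, a.duration - shared


def phenology_ri(shared: float, unshared: float) -> float:
    """Phenological isolation ``1 - S/(S+U)`` for one focal direction.

    ``shared`` and ``unshared`` may be day counts or proportions; the
    result is the unshared fraction of the focal taxon's flowering time,
    in [0, 1].
    """
    if shared < 0 or unshared < 0:
        raise InvalidInputError("shared/unshared times must be nonnegative")
    total = shared + unshared
    if total == 0:
        raise UndefinedRIError("S = U = 0: no flowering time, RI undefined")
    return 1.0 - shared / total


def pairwise_ri(pair: SuccessPair | None = None, *, conspecific: float | None = None,
                heterospecific: float | None = None) -> float:
    """Paired-success isolation ``1 - 2*H/(H+C)`` in [-1, 1].

    Accepts either a :class:`SuccessPair` or explicit keyword ``conspecific``
    / ``heterospecific`` values.  1 means complete isolation (H = 0), 0 means
    no isolation (H = C), and negative values a heterospecific advantage.
    """
    if pair is not None:
        c, h = pair.conspecific, pair.heterospecific
    else:
        if conspecific is None or heterospecific is None:
            raise InvalidInputError("pass a SuccessPair or both C and H")
        # route through the record so its validation applies
        c, h = dataclasses.astuple(SuccessPair(conspecific, heterospecific))[:2]
    return 1.0 - 2.0 * h / (h + c)


def asymmetry(ri_dir1: float, ri_dir2: float) -> float:
    """Directional asymmetry of a barrier: ``|RI_dir1 - RI_dir2|``.

    Computed on unrounded inputs; round only at report time.
    """
    if not (np.isfinite(ri_dir1) and np.isfinite(ri_dir2)):
        raise InvalidInputError("asymmetry requires finite RI values")
    return abs(ri_dir1 - ri_dir2)


def bootstrap_ci(
    conspecific_obs: Sequence[float],
    heterospecific_obs: Sequence[float],
    b: int = 2000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    statistic: Callable[[np.ndarray], float] = np.mean,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a paired-success RI.

    Resamples the conspecific and heterospecific observation vectors
    independently with replacement, summarises each resample with
    ``statistic`` (the mean by default) and recomputes the RI.  Degenerate
    resamples with C = H = 0 carry no information and are skipped with a
    logged warning.  Reproducible under a fixed ``seed``.
    """
    cons = np.asarray(conspecific_obs, dtype=float)
    het = np.asarray(heterospecific_obs, dtype=float)
    if cons.size < 2 or het.size < 2:
        raise InvalidInputError("bootstrap needs >= 2 observations per class")
    if b < 100:
        raise InvalidInputError("use at least B = 100 bootstrap resamples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    c_idx = rng.integers(0, cons.size, size=(b, cons.size))
    h_idx = rng.integers(0, het.size, size=(b, het.size))
    if statistic is np.mean:  # fast path for the default
        c_stat = cons[c_idx].mean(axis=1)
        h_stat = het[h_idx].mean(axis=1)
    else:
        c_stat = np.apply_along_axis(statistic, 1, cons[c_idx])
        h_stat = np.apply_along_axis(statistic, 1, het[h_idx])

    ok = (c_stat + h_stat) > 0
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.warning("skipped %d degenerate bootstrap resamples (C = H = 0)", n_degenerate)
    ris = 1.0 - 2.0 * h_stat[ok] / (h_stat[ok] + c_stat[ok])
    if ris.size == 0:
        raise UndefinedRIError("every bootstrap resample was degenerate")
    low, high = np.quantile(ris, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)
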