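"""Sequential composition of reproductive barriers into total isolation.

Barriers act in life-history order: phenological overlap first, then
pollinator foraging, pollinia–pistil interaction, fruit production and
seed development.  Each post-phenology barrier enters the cascade through
its *relative heterospecific success* ``h = H/C`` (1 = no isolation,
0 = absolute barrier, > 1 = heterospecific advantage).  Relative successes
multiply across stages — the composite heterospecific effect after stage
``i`` is ``prod(h_1..h_i)`` — and heterospecific mating is confined to the
co-flowering window.

With ``S`` the shared and ``U = 1 - S`` the unshared fraction of the focal
form's flowering season, no heterospecific success outside the shared
window, and conspecific success identical in the two windows (normalised
to 1), the cumulative isolation through stage ``i`` (stage 1 = phenology
alone) is::

    RI[1,1] = 1 - S/(S+U) = U
    RI[1,i] = 1 - 2 * S*prod(h_1..h_{i-1}) / (S*prod(h_1..h_{i-1}) + 1),  i >= 2

The two conventions (no factor 2 for phenology, factor 2 thereafter) are
the standard usage in the sequential-barrier literature and are kept
deliberately: they are not mutually consistent in the full-overlap limit,
but each matches how single-barrier strengths are reported.

Per-barrier contributions are read off the cumulative sequence:
``AC_i = RI[1,i] - RI[1,i-1]`` with ``RI[1,0] = 0`` (so the contributions
telescope to the total exactly), and ``RC_i = AC_i / RI_total``.
Contributions are order-dependent; reports state the order used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .barrier_metrics import SuccessPair, asymmetry, pairwise_ri, phenology_ri
from .errors import InvalidInputError, UndefinedRIError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BARRIER_ORDER",
    "BarrierCascade",
    "CascadeResult",
    "relative_success",
    "invert_relative_success",
    "cumulative_ri",
    "contributions",
    "total_ri_both_directions",
]

#: Life-history order of the post-phenology barriers.
DEFAULT_BARRIER_ORDER: tuple[str, ...] = (
    "pollinator",
    "pollen_tube",
    "fruit_set",
    "seed_development",
)


def relative_success(pair: SuccessPair) -> float:
    """Relative heterospecific success ``h = H/C`` for one barrier stage.

    Values above 1 (anti-isolation) are legitimate.  A stage with C = 0
    cannot be normalised this way; its strength is only expressible as an
    RI — compute it with :func:`isobarrier.barrier_metrics.pairwise_ri`.
    """
    if pair.conspecific == 0:
        raise InvalidInputError(
            f"C = 0 for barrier {pair.barrier!r}: relative success H/C is "
            "undefined; use pairwise_ri for the single-barrier strength"
        )
    return pair.heterospecific / pair.conspecific


def invert_relative_success(ri: float) -> float:
    """Recover ``h = H/C`` from a published paired-success RI.

    Inverts ``RI = 1 - 2h/(h+1)`` to ``h = (1-RI)/(1+RI)``.  Useful when a
    study prints a barrier's RI but not the underlying success rates.
    """
    if not -1.0 < ri <= 1.0:
        raise InvalidInputError(f"paired-success RI must lie in (-1, 1], got {ri}")
    logger.info("inverting published RI=%.4f to relative success h=%.4f",
                ri, (1 - ri) / (1 + ri))
    return (1.0 - ri) / (1.0 + ri)


@dataclass(frozen=True)
class BarrierCascade:
    """One maternal direction's ordered barrier sequence.

    ``shared`` is the proportion S of the maternal form's flowering time
    shared with the other form; ``barriers`` are the post-phenology stages
    in the order they act.
    """

    maternal_form: str
    shared: float
    barriers: tuple[SuccessPair, ...]

    def __init__(self, maternal_form: str, shared: float,
                 barriers: Sequence[SuccessPair]):
        if not 0.0 <= shared <= 1.0:
            raise InvalidInputError(f"shared proportion must be in [0,1], got {shared}")
        for b in barriers:
            if b.conspecific == 0:
                raise InvalidInputError(
                    f"cascade barrier {b.barrier!r} has C = 0; cascades require "
                    "C > 0 so that h = H/C exists"
                )
        object.__setattr__(self, "maternal_form", maternal_form)
        object.__setattr__(self, "shared", float(shared))
        object.__setattr__(self, "barriers", tuple(barriers))

    @property
    def unshared(self) -> float:
        return 1.0 - self.shared

    @property
    def n_stages(self) -> int:
        """Number of stages including phenology as stage 1."""
        return len(self.barriers) + 1

    @property
    def stage_names(self) -> tuple[str, ...]:
        return ("phenology",) + tuple(b.barrier for b in self.barriers)

    def relative_successes(self) -> list[float]:
        return [relative_success(b) for b in self.barriers]


@dataclass(frozen=True)
class CascadeResult:
    """Cumulative RIs and per-barrier contributions for one direction."""

    maternal_form: str
    stage_names: tuple[str, ...]
    cumulative_ri: tuple[float, ...]
    total_ri: float
    abs_contrib: tuple[float, ...]
    rel_contrib: tuple[float, ...] | None = field(default=None)

    def as_records(self) -> list[dict]:
        """Tidy per-stage records (for DataFrame/TSV rendering)."""
        rows = []
        for i, name in enumerate(self.stage_names):
            rows.append({
                "maternal_form": self.maternal_form,
                "stage": i + 1,
                "barrier": name,
                "cumulative_ri": self.cumulative_ri[i],
                "abs_contribution": self.abs_contrib[i],
                "rel_contribution": (None if self.rel_contrib is None
                                     else self.rel_contrib[i]),
            })
        return rows


def cumulative_ri(cascade: BarrierCascade, stage: int) -> float:
    """Cumulative isolation through ``stage`` (1-based; stage 1 = phenology)."""
    if not 1 <= stage <= cascade.n_stages:
        raise InvalidInputError(
            f"stage {stage} out of range 1..{cascade.n_stages}"
        )
    if stage == 1:
        return phenology_ri(cascade.shared, cascade.unshared)
    h = math.prod(cascade.relative_successes()[: stage - 1])
    sh = cascade.shared * h
    return 1.0 - 2.0 * sh / (sh + 1.0)


def contributions(cascade: BarrierCascade) -> CascadeResult:
    """Cumulative RIs, total RI and absolute/relative contributions.

    Absolute contributions telescope to the total exactly.  Relative
    contributions are undefined (``None``) when the total is 0.
    """
    cum = [cumulative_ri(cascade, i) for i in range(1, cascade.n_stages + 1)]
    total = cum[-1]
    prev = [0.0] + cum[:-1]
    ac = [c - p for c, p in zip(cum, prev)]
    if total == 0.0:
        logger.warning("total RI is 0 for %r: relative contributions undefined",
                       cascade.maternal_form)
        rc = None
    else:
        rc = tuple(a / total for a in ac)
    return CascadeResult(
        maternal_form=cascade.maternal_form,
        stage_names=cascade.stage_names,
        cumulative_ri=tuple(cum),
        total_ri=total,
        abs_contrib=tuple(ac),
        rel_contrib=rc,
    )


def total_ri_both_directions(
    cascade_a: BarrierCascade, cascade_b: BarrierCascade
) -> tuple[CascadeResult, CascadeResult, dict[str, float]]:
    """Compose both maternal directions and their per-stage asymmetries.

    The two cascades must list the same barriers in the same order.
    Returns ``(result_a, result_b, {stage_name: |RI_a - RI_b|})`` where the
    asymmetries compare the *single-stage* strengths (phenology RI for
    stage 1, paired-success RI per barrier thereafter) plus a
    ``"total"`` entry comparing the cumulative totals.
    """
    if cascade_a.stage_names != cascade_b.stage_names:
        raise InvalidInputError(
            f"mismatched barrier order: {cascade_a.stage_names} vs "
            f"{cascade_b.stage_names}"
        )
    res_a = contributions(cascade_a)
    res_b = contributions(cascade_b)

    asym: dict[str, float] = {
        "phenology": asymmetry(
            phenology_ri(cascade_a.shared, cascade_a.unshared),
            phenology_ri(cascade_b.shared, cascade_b.unshared),
        )
    }
    for pa, pb in zip(cascade_a.barriers, cascade_b.barriers):
        asym[pa.barrier] = asymmetry(pairwise_ri(pa), pairwise_ri(pb))
    asym["total"] = asymmetry(res_a.total_ri, res_b.total_ri)
    return res_a, res_b, asym
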