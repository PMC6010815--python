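"""Pollinator foraging sequences: transition tables and floral constancy.

A forager's observed behaviour is a set of *bouts*, each an ordered
sequence of plant visits labelled by colour form.  Transitions are
consecutive moves between distinct plants within one bout (repeat visits
to the same plant are collapsed first; bouts are never bridged).

Floral constancy per forager uses Gegear's index::

    CI = (c - e) / ((c + e) - 2*c*e),   e = p**2 + (1-p)**2

where ``c`` is the forager's observed proportion of same-form transitions
and ``p`` its proportion of visits to the focal form.  CI runs from -1
(complete inconstancy) through 0 (random foraging given availability) to
1 (complete constancy).  ``e`` is symmetric in ``p <-> 1-p``, so either
form may serve as focal; the first label alphabetically is used for
determinism.

The pooled transition table also yields the pollinator-isolation success
pair for each maternal direction: conspecific success is the count of
same-form arrivals at that form, heterospecific success the count of
cross-form arrivals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .barrier_metrics import SuccessPair
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "ForagingBout",
    "TransitionTable",
    "ConstancyRecord",
    "tabulate_transitions",
    "gegear_ci",
    "forager_constancy",
    "pollinator_success_pairs",
    "species_ci_summary",
]


@dataclass(frozen=True)
class ForagingBout:
    """One forager's ordered visit sequence (plant id, form label)."""

    forager_id: str
    species: str
    visits: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.visits) < 1:
            raise InvalidInputError(f"bout of {self.forager_id!r} has no visits")

    def collapsed(self) -> list[tuple[str, str]]:
        """Visits with consecutive same-plant repeats merged."""
        out: list[tuple[str, str]] = []
        for v in self.visits:
            if not out or v[0] != out[-1][0]:
                out.append(v)
        return out

    def transitions(self) -> list[tuple[str, str]]:
        """Consecutive (form_from, form_to) moves between distinct plants."""
        coll = self.collapsed()
        return [(a[1], b[1]) for a, b in zip(coll, coll[1:])]


@dataclass(frozen=True)
class TransitionTable:
    """2x2 counts of plant-to-plant moves between two colour forms."""

    forms: tuple[str, str]
    counts: tuple[tuple[int, int], tuple[int, int]]  # counts[from][to]

    def __post_init__(self) -> None:
        if len(self.forms) != 2 or self.forms[0] == self.forms[1]:
            raise InvalidInputError("TransitionTable needs two distinct form labels")
        if any(c < 0 for row in self.counts for c in row):
            raise InvalidInputError("transition counts must be nonnegative")

    def count(self, frm: str, to: str) -> int:
        return self.counts[self.forms.index(frm)][self.forms.index(to)]

    @property
    def total(self) -> int:
        return sum(c for row in self.counts for c in row)

    @property
    def intraform_share(self) -> float:
        if self.total == 0:
            raise InvalidInputError("empty transition table")
        return (self.counts[0][0] + self.counts[1][1]) / self.total

    def to_dict(self) -> dict:
        a, b = self.forms
        return {
            f"{a}->{a}": self.counts[0][0], f"{a}->{b}": self.counts[0][1],
            f"{b}->{a}": self.counts[1][0], f"{b}->{b}": self.counts[1][1],
            "total": self.total,
        }


@dataclass(frozen=True)
class ConstancyRecord:
    """Per-forager constancy summary; ``ci`` is NaN when undefined."""

    forager_id: str
    species: str
    c: float
    p: float
    e: float
    ci: float
    n_transitions: int


def tabulate_transitions(
    bouts: Iterable[ForagingBout], forms: tuple[str, str]
) -> tuple[TransitionTable, dict[str, TransitionTable]]:
    """Pooled and per-forager transition tables from a set of bouts.

    Transitions never bridge bouts; bouts visiting fewer than two distinct
    plants contribute no transitions (logged).  Unknown form labels raise.
    """
    idx = {f: i for i, f in enumerate(forms)}
    pooled = np.zeros((2, 2), dtype=int)
    per: dict[str, np.ndarray] = {}
    for bout in bouts:
        for _, form in bout.visits:
            if form not in idx:
                raise InvalidInputError(
                    f"unknown form label {form!r}; declared forms: {forms}"
                )
        trans = bout.transitions()
        if not trans:
            logger.info("bout of %r visits < 2 distinct plants; no transitions",
                        bout.forager_id)
        tab = per.setdefault(bout.forager_id, np.zeros((2, 2), dtype=int))
        for frm, to in trans:
            tab[idx[frm], idx[to]] += 1
            pooled[idx[frm], idx[to]] += 1

    def _wrap(arr: np.ndarray) -> TransitionTable:
        return TransitionTable(forms, tuple(tuple(int(x) for x in row) for row in arr))

    return _wrap(pooled), {fid: _wrap(t) for fid, t in per.items()}


def gegear_ci(c: float, p: float) -> float:
    """Gegear's constancy index from same-form transition and visit proportions.

    Returns NaN when the denominator vanishes (c = e = 0 or c = e = 1),
    i.e. when constancy is uninformative.
    """
    if not (0.0 <= c <= 1.0 and 0.0 <= p <= 1.0):
        raise InvalidInputError(f"c and p must be proportions, got c={c}, p={p}")
    e = p * p + (1.0 - p) * (1.0 - p)
    denom = (c + e) - 2.0 * c * e
    if denom == 0.0:
        return math.nan
    return (c - e) / denom


def forager_constancy(
    bouts: Sequence[ForagingBout], forms: tuple[str, str],
    expected_share: float | None = None,
) -> list[ConstancyRecord]:
    """Per-forager constancy over each forager's whole observed bout set.

    ``c`` pools transitions across the forager's bouts (without bridging);
    ``p`` is its visit share to the focal form (first label after sorting).
    Foragers with no transitions get CI = NaN.

    The expected same-form proportion ``e`` defaults to the forager's own
    visit share (``e = p^2 + (1-p)^2``).  That convention leaves CI
    undefined for a forager that only ever visits one form (c = e = 1).
    When the floral array's composition is known — e.g. an experimental
    20:20 choice array — pass the focal form's availability as
    ``expected_share`` so that ``e`` reflects what random foraging over
    the array would produce; a perfectly constant forager then scores
    CI = 1.
    """
    focal = sorted(forms)[0]
    by_forager: dict[str, list[ForagingBout]] = {}
    for b in bouts:
        by_forager.setdefault(b.forager_id, []).append(b)

    records = []
    for fid, fb in by_forager.items():
        trans = [t for b in fb for t in b.transitions()]
        visits = [v for b in fb for v in b.collapsed()]
        species = fb[0].species
        n = len(trans)
        if n == 0:
            records.append(ConstancyRecord(fid, species, math.nan, math.nan,
                                           math.nan, math.nan, 0))
            continue
        c = sum(1 for frm, to in trans if frm == to) / n
        p = sum(1 for _, form in visits if form == focal) / len(visits)
        p_e = p if expected_share is None else expected_share
        e = p_e * p_e + (1 - p_e) * (1 - p_e)
        records.append(ConstancyRecord(fid, species, c, p, e, gegear_ci(c, p_e), n))
    return records


def pollinator_success_pairs(table: TransitionTable) -> dict[str, SuccessPair]:
    """Pollinator-isolation success pair per maternal form.

    For maternal form X: C = same-form arrivals X->X, H = cross-form
    arrivals at X.
    """
    if table.total == 0:
        raise InvalidInputError("all-zero transition table")
    a, b = table.forms
    return {
        a: SuccessPair(conspecific=table.count(a, a), heterospecific=table.count(b, a),
                       maternal_form=a, barrier="pollinator", n=table.total),
        b: SuccessPair(conspecific=table.count(b, b), heterospecific=table.count(a, b),
                       maternal_form=b, barrier="pollinator", n=table.total),
    }


def species_ci_summary(records: Iterable[ConstancyRecord]) -> pd.DataFrame:
    """Mean +/- SD constancy per species, excluding undefined CIs.

    Columns: species, mean_ci, sd_ci, n, n_undefined.  SD is the sample
    standard deviation, reported as 0.0 for a single forager.
    """
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise InvalidInputError("no constancy records")
    rows = []
    for species, grp in df.groupby("species", sort=True):
        defined = grp["ci"].dropna()
        if defined.empty:
            logger.warning("species %r has no defined CI values", species)
        rows.append({
            "species": species,
            "mean_ci": float(defined.mean()) if len(defined) else math.nan,
            "sd_ci": float(defined.std(ddof=1)) if len(defined) > 1 else
                     (0.0 if len(defined) == 1 else math.nan),
            "n": int(len(defined)),
            "n_undefined": int(grp["ci"].isna().sum()),
        })
    return pd.DataFrame(rows)
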