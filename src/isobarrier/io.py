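"""Readers and writers for the study's file formats.

All tabular formats are plain CSV/TSV with a header row; dates are
ISO-8601 and day arithmetic everywhere is inclusive of both endpoints.
Readers validate schemas and report offending rows; writers round-trip
losslessly (two-decimal rounding happens only in rendered reports).

Formats
-------
flowering CSV      ``form, first_day, last_day``
foraging log CSV   ``forager_id, species, visit_index, plant_id, form``
transition CSV     ``from_form, to_form, count``
crossing CSV       ``maternal_form, treatment, replicate, fruit,
                   pollen_tubes, n_large, n_small, n_aborted, n_empty``
barrier-pair CSV   ``barrier, maternal_form, conspecific, heterospecific,
                   ri, n`` — give (C, H) when rates are known, or a bare
                   published ``ri`` to be inverted to ``h=(1-RI)/(1+RI)``
spectra CSV        ``wavelength_nm`` plus one column per spectrum
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .barrier_metrics import FloweringInterval, SuccessPair
from .bee_vision import Spectrum
from .cascade import invert_relative_success
from .constancy import ForagingBout, TransitionTable
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "read_flowering_csv", "write_flowering_csv",
    "read_foraging_csv", "write_foraging_csv",
    "read_transitions_csv", "write_transitions_csv",
    "read_crossing_csv", "write_crossing_csv",
    "read_barrier_pairs_csv",
    "read_spectra_csv", "write_spectra_csv",
    "load_yaml",
]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InvalidInputError(f"empty input file: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    if df.empty:
        raise InvalidInputError(f"{path}: no data rows")
    return df


def _parse_date(value: str, path: Path, line: int) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError:
        raise InvalidInputError(
            f"{path}, row {line}: {value!r} is not an ISO-8601 date"
        ) from None


def read_flowering_csv(path: str | Path) -> dict[str, FloweringInterval]:
    """Form-level flowering intervals keyed by form label."""
    path = Path(path)
    df = _read_table(path, ["form", "first_day", "last_day"])
    out: dict[str, FloweringInterval] = {}
    for i, row in df.iterrows():
        out[str(row["form"])] = FloweringInterval(
            str(row["form"]),
            _parse_date(row["first_day"], path, i + 2),
            _parse_date(row["last_day"], path, i + 2),
        )
    return out


def write_flowering_csv(intervals: Iterable[FloweringInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"form": iv.form, "first_day": iv.first_day.isoformat(),
          "last_day": iv.last_day.isoformat()} for iv in intervals]
    ).to_csv(path, index=False)


def read_foraging_csv(path: str | Path) -> list[ForagingBout]:
    """Foraging log rows grouped into per-forager bouts.

    A ``bout_id`` column separates bouts; without one, each forager's rows
    (ordered by ``visit_index``) form a single bout.
    """
    df = _read_table(path, ["forager_id", "species", "visit_index", "plant_id", "form"])
    group_cols = ["forager_id", "bout_id"] if "bout_id" in df.columns else ["forager_id"]
    bouts = []
    for _, grp in df.groupby(group_cols, sort=True):
        grp = grp.sort_values("visit_index")
        bouts.append(ForagingBout(
            forager_id=str(grp["forager_id"].iloc[0]),
            species=str(grp["species"].iloc[0]),
            visits=tuple(zip(grp["plant_id"].astype(str), grp["form"].astype(str))),
        ))
    return bouts


def write_foraging_csv(bouts: Iterable[ForagingBout], path: str | Path) -> None:
    rows = []
    for b_i, bout in enumerate(bouts):
        for v_i, (plant, form) in enumerate(bout.visits):
            rows.append({"forager_id": bout.forager_id, "species": bout.species,
                         "bout_id": b_i, "visit_index": v_i,
                         "plant_id": plant, "form": form})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transitions_csv(path: str | Path, forms: tuple[str, str]) -> TransitionTable:
    """A pre-tabulated transition-count table (``from_form,to_form,count``)."""
    df = _read_table(path, ["from_form", "to_form", "count"])
    counts = np.zeros((2, 2), dtype=int)
    idx = {f: i for i, f in enumerate(forms)}
    for i, row in df.iterrows():
        frm, to = str(row["from_form"]), str(row["to_form"])
        if frm not in idx or to not in idx:
            raise InvalidInputError(
                f"{path}, row {i + 2}: unknown form in {frm!r}->{to!r}; "
                f"declared forms: {forms}"
            )
        counts[idx[frm], idx[to]] += int(row["count"])
    return TransitionTable(forms, tuple(tuple(int(x) for x in r) for r in counts))


def write_transitions_csv(table: TransitionTable, path: str | Path) -> None:
    a, b = table.forms
    rows = [{"from_form": f, "to_form": t, "count": table.count(f, t)}
            for f in (a, b) for t in (a, b)]
    pd.DataFrame(rows).to_csv(path, index=False)


CROSSING_COLUMNS = ["maternal_form", "treatment", "replicate", "fruit",
                    "pollen_tubes", "n_large", "n_small", "n_aborted", "n_empty"]


def read_crossing_csv(path: str | Path) -> pd.DataFrame:
    """Raw hand-pollination trials, one row per treated flower."""
    df = _read_table(path, CROSSING_COLUMNS)
    if not df["fruit"].isin([0, 1]).all():
        bad = df.index[~df["fruit"].isin([0, 1])][0] + 2
        raise InvalidInputError(f"{path}, row {bad}: fruit must be 0 or 1")
    return df


def write_crossing_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_barrier_pairs_csv(path: str | Path) -> list[SuccessPair]:
    """Success pairs per barrier and maternal direction.

    Rows carrying ``conspecific``/``heterospecific`` are used verbatim.
    Rows with only a published ``ri`` are converted to a normalised pair
    (C = 1, H = (1-RI)/(1+RI)); each inversion is logged.
    """
    path = Path(path)
    df = _read_table(path, ["barrier", "maternal_form"])
    pairs = []
    for i, row in df.iterrows():
        c = row.get("conspecific")
        h = row.get("heterospecific")
        n = row.get("n")
        n = int(n) if pd.notna(n) else None
        if pd.notna(c) and pd.notna(h):
            pairs.append(SuccessPair(float(c), float(h),
                                     str(row["maternal_form"]), str(row["barrier"]), n))
        elif pd.notna(row.get("ri")):
            logger.info("%s row %d: only an RI is given for %s/%s; inverting to h",
                        path, i + 2, row["barrier"], row["maternal_form"])
            pairs.append(SuccessPair(1.0, invert_relative_success(float(row["ri"])),
                                     str(row["maternal_form"]), str(row["barrier"]), n))
        else:
            raise InvalidInputError(
                f"{path}, row {i + 2}: need either (conspecific, heterospecific) or ri"
            )
    return pairs


def read_spectra_csv(path: str | Path, kind: str = "reflectance") -> list[Spectrum]:
    """One spectrum per non-wavelength column; first column is wavelength_nm."""
    df = _read_table(path, ["wavelength_nm"])
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    spectra = []
    for col in df.columns[1:]:
        spectra.append(Spectrum(wl, df[col].to_numpy(dtype=float),
                                kind=kind, name=str(col)))
    if not spectra:
        raise InvalidInputError(f"{path}: no spectrum columns besides wavelength_nm")
    return spectra


def write_spectra_csv(spectra: Sequence[Spectrum], path: str | Path) -> None:
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise InvalidInputError("spectra must share one wavelength grid to share a file")
    data = {"wavelength_nm": wl}
    data.update({s.name or f"spectrum_{i}": s.values for i, s in enumerate(spectra)})
    pd.DataFrame(data).to_csv(path, index=False)


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: expected a YAML mapping")
    return data
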