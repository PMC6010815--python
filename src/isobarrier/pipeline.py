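"""End-to-end analysis: files in, barrier/cascade/constancy/vision tables out.

The pipeline composes the library modules over a declarative
:class:`StudyConfig`:

1. phenology — flowering intervals -> shared/unshared days -> phenological
   RI per maternal direction;
2. pollinator — a foraging log (tabulated) or a pre-counted transition
   table -> pollinator success pairs, plus per-forager constancy when the
   log is available;
3. post-pollination — raw crossing trials (summarised to pollen-tube,
   fruit-set and seed-development pairs) and/or a barrier-pair file;
4. cascade — both maternal directions composed in the configured barrier
   order, with per-stage contributions and asymmetries;
5. vision (optional) — reflectance spectra -> hexagon loci, pairwise
   chromatic distances and JND discriminability flags.

Outputs are TSV tables plus one summary JSON; numbers are serialised at
full precision and rounded only in the ``*_2dp`` report fields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iomod
from .barrier_metrics import (BarrierEstimate, SuccessPair, asymmetry,
                              bootstrap_ci, overlap_days, pairwise_ri,
                              phenology_ri, round_half_up)
from .bee_vision import (VisionModel, chromatic_distance, discriminable,
                         locus_of)
from .cascade import (DEFAULT_BARRIER_ORDER, BarrierCascade, contributions,
                      total_ri_both_directions)
from .constancy import (forager_constancy, pollinator_success_pairs,
                        species_ci_summary, tabulate_transitions)
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "summarize_crossings", "run_pipeline"]

SUMMARY_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class StudyConfig:
    """Paths and options for one full study analysis.

    Exactly one of ``foraging``/``transitions`` supplies the pollinator
    stage; ``crossing`` (raw trials) and ``barrier_pairs`` (summaries)
    may be combined, with raw trials taking precedence per barrier.
    """

    forms: tuple[str, str] = ("white", "pink")
    phenology: Path | None = None
    foraging: Path | None = None
    transitions: Path | None = None
    crossing: Path | None = None
    barrier_pairs: Path | None = None
    spectra: Path | None = None
    barrier_order: tuple[str, ...] = DEFAULT_BARRIER_ORDER
    vision_model: str = "honeybee"
    jnd_threshold: float = 0.1
    bootstrap_b: int = 2000
    seed: int = 0
    out_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        """Load a config mapping; relative paths resolve against the file."""
        path = Path(path)
        raw = iomod.load_yaml(path)
        base = path.parent
        kwargs: dict = {}
        for key in ("phenology", "foraging", "transitions", "crossing",
                    "barrier_pairs", "spectra", "out_dir"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                kwargs[key] = p if p.is_absolute() else base / p
        for key in ("vision_model", "jnd_threshold", "bootstrap_b", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "forms" in raw:
            kwargs["forms"] = tuple(raw["forms"])
        if "barrier_order" in raw:
            kwargs["barrier_order"] = tuple(raw["barrier_order"])
        cfg = cls(**kwargs)
        for key in ("phenology", "foraging", "transitions", "crossing",
                    "barrier_pairs", "spectra"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise InvalidInputError(f"config {key} file does not exist: {p}")
        return cfg


def summarize_crossings(trials: pd.DataFrame, forms: tuple[str, str]
                        ) -> tuple[list[SuccessPair], dict]:
    """Collapse raw crossing trials to per-barrier success pairs.

    Per maternal form: pollen-tube pair = mean tubes (intraform vs
    interform rows); fruit-set pair = fruit proportion; seed-development
    pair = mean per-fruit large-embryo rate over fruiting flowers.  The
    raw per-flower observations behind each pair are returned alongside
    for bootstrapping.
    """
    pairs: list[SuccessPair] = []
    raw_obs: dict = {}
    for form in forms:
        sub = trials[trials["maternal_form"] == form]
        if sub.empty:
            raise InvalidInputError(f"no crossing trials for maternal form {form!r}")
        intra = sub[sub["treatment"] == "intraform"]
        inter = sub[sub["treatment"] == "interform"]
        if intra.empty or inter.empty:
            raise InvalidInputError(
                f"crossing trials for {form!r} need both intraform and interform rows"
            )

        def _seed_rates(rows: pd.DataFrame) -> np.ndarray:
            seeded = rows[rows["fruit"] == 1]
            totals = seeded[["n_large", "n_small", "n_aborted", "n_empty"]].sum(axis=1)
            ok = totals > 0
            return (seeded.loc[ok, "n_large"] / totals[ok]).to_numpy()

        obs = {
            "pollen_tube": (intra["pollen_tubes"].to_numpy(float),
                            inter["pollen_tubes"].to_numpy(float)),
            "fruit_set": (intra["fruit"].to_numpy(float),
                          inter["fruit"].to_numpy(float)),
            "seed_development": (_seed_rates(intra), _seed_rates(inter)),
        }
        for barrier, (c_obs, h_obs) in obs.items():
            if c_obs.size == 0 or h_obs.size == 0:
                logger.warning("no observations for %s/%s; barrier skipped",
                               barrier, form)
                continue
            pairs.append(SuccessPair(float(c_obs.mean()), float(h_obs.mean()),
                                     form, barrier,
                                     n=int(c_obs.size + h_obs.size)))
            raw_obs[(barrier, form)] = (c_obs, h_obs)
    return pairs, raw_obs


def _barrier_table(estimates: list[BarrierEstimate],
                   asymmetries: dict[str, float]) -> pd.DataFrame:
    rows = []
    for est in estimates:
        rows.append({
            "barrier": est.barrier,
            "maternal_form": est.maternal_form,
            "conspecific": est.conspecific,
            "heterospecific": est.heterospecific,
            "n": est.n,
            "ri": est.ri,
            "ri_2dp": round_half_up(est.ri),
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "asymmetry": asymmetries.get(est.barrier),
            "asymmetry_2dp": (round_half_up(asymmetries[est.barrier])
                              if est.barrier in asymmetries else None),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig) -> dict:
    """Run every configured stage; returns the report bundle as a dict.

    Keys: ``barriers`` (DataFrame), ``cascade`` (DataFrame), ``constancy``
    (DataFrames or None), ``transitions`` (dict or None), ``vision``
    (dict or None) and ``summary`` (JSON-ready dict).  When
    ``config.out_dir`` is set, TSV/JSON files are also written there.
    """
    form_a, form_b = config.forms
    rng = np.random.default_rng(config.seed)
    estimates: list[BarrierEstimate] = []
    single_ri: dict[tuple[str, str], float] = {}

    # --- stage 1: phenology ------------------------------------------------
    if config.phenology is None:
        raise InvalidInputError("a phenology file is required")
    intervals = iomod.read_flowering_csv(config.phenology)
    for form in config.forms:
        if form not in intervals:
            raise InvalidInputError(f"phenology file lacks form {form!r}")
    shared_a, unshared_a = overlap_days(intervals[form_a], intervals[form_b])
    shared_b, unshared_b = overlap_days(intervals[form_b], intervals[form_a])
    phen = {form_a: phenology_ri(shared_a, unshared_a),
            form_b: phenology_ri(shared_b, unshared_b)}
    for form, (s, u) in ((form_a, (shared_a, unshared_a)),
                         (form_b, (shared_b, unshared_b))):
        single_ri[("phenology", form)] = phen[form]
        estimates.append(BarrierEstimate("phenology", form, phen[form],
                                         conspecific=s, heterospecific=u))

    # --- stage 2: pollinator ----------------------------------------------
    constancy_out = None
    transitions_out = None
    pair_map: dict[tuple[str, str], SuccessPair] = {}
    if config.foraging is not None:
        bouts = iomod.read_foraging_csv(config.foraging)
        table, _ = tabulate_transitions(bouts, config.forms)
        records = forager_constancy(bouts, config.forms)
        constancy_out = {
            "foragers": pd.DataFrame([r.__dict__ for r in records]),
            "species": species_ci_summary(records),
        }
    elif config.transitions is not None:
        table = iomod.read_transitions_csv(config.transitions, config.forms)
    else:
        table = None
    if table is not None:
        transitions_out = table.to_dict()
        for form, pair in pollinator_success_pairs(table).items():
            pair_map[("pollinator", form)] = pair

    # --- stages 3-5: post-pollination barriers -----------------------------
    raw_obs: dict = {}
    if config.barrier_pairs is not None:
        for pair in iomod.read_barrier_pairs_csv(config.barrier_pairs):
            pair_map[(pair.barrier, pair.maternal_form)] = pair
    if config.crossing is not None:
        trials = iomod.read_crossing_csv(config.crossing)
        pairs, raw_obs = summarize_crossings(trials, config.forms)
        for pair in pairs:  # raw trials take precedence over summaries
            pair_map[(pair.barrier, pair.maternal_form)] = pair

    for (barrier, form), pair in sorted(pair_map.items()):
        est = BarrierEstimate.from_pair(pair)
        if (barrier, form) in raw_obs:
            c_obs, h_obs = raw_obs[(barrier, form)]
            if c_obs.size >= 2 and h_obs.size >= 2:
                est = est.with_ci(*bootstrap_ci(c_obs, h_obs, b=config.bootstrap_b,
                                                seed=rng))
        single_ri[(barrier, form)] = est.ri
        estimates.append(est)

    asymmetries = {
        barrier: asymmetry(single_ri[(barrier, form_a)], single_ri[(barrier, form_b)])
        for barrier in ["phenology", *config.barrier_order]
        if (barrier, form_a) in single_ri and (barrier, form_b) in single_ri
    }
    barrier_df = _barrier_table(estimates, asymmetries)

    # --- cascade ------------------------------------------------------------
    cascade_df = None
    cascade_summary = None
    missing = [(b, f) for b in config.barrier_order for f in config.forms
               if (b, f) not in pair_map]
    if missing:
        logger.warning("cascade skipped; missing barrier pairs: %s", missing)
    else:
        durations = {form_a: shared_a + unshared_a, form_b: shared_b + unshared_b}
        shared_days = {form_a: shared_a, form_b: shared_b}
        cascades = {
            form: BarrierCascade(
                form, shared_days[form] / durations[form],
                [pair_map[(b, form)] for b in config.barrier_order])
            for form in config.forms
        }
        res_a, res_b, stage_asym = total_ri_both_directions(
            cascades[form_a], cascades[form_b])
        cascade_df = pd.DataFrame(res_a.as_records() + res_b.as_records())
        cascade_summary = {
            "barrier_order": list(("phenology",) + config.barrier_order),
            "total_ri": {form_a: res_a.total_ri, form_b: res_b.total_ri},
            "total_ri_2dp": {form_a: round_half_up(res_a.total_ri),
                             form_b: round_half_up(res_b.total_ri)},
            "stage_asymmetry": stage_asym,
        }

    # --- vision -------------------------------------------------------------
    vision_out = None
    if config.spectra is not None:
        model = {"honeybee": VisionModel.honeybee,
                 "bumblebee": VisionModel.bumblebee}.get(config.vision_model)
        if model is None:
            raise InvalidInputError(
                f"unknown vision model {config.vision_model!r}; "
                "choose honeybee or bumblebee"
            )
        model = model()
        spectra = iomod.read_spectra_csv(config.spectra)
        loci = {s.name: locus_of(s, model) for s in spectra}
        names = list(loci)
        dist = pd.DataFrame(
            [[chromatic_distance(loci[a], loci[b]) for b in names] for a in names],
            index=names, columns=names)
        flags = dist.map(lambda d: discriminable(d, config.jnd_threshold)[0])
        vision_out = {
            "model": model.metadata(),
            "jnd_threshold": config.jnd_threshold,
            "loci": pd.DataFrame(
                [{"spectrum": n, "e_uv": l.e_uv, "e_b": l.e_b, "e_g": l.e_g,
                  "x": l.x, "y": l.y} for n, l in loci.items()]),
            "distances": dist,
            "discriminable": flags,
        }

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "forms": list(config.forms),
        "seed": config.seed,
        "barriers": {
            f"{est.barrier}/{est.maternal_form}": {
                "ri": est.ri, "ri_2dp": round_half_up(est.ri),
                "conspecific": est.conspecific,
                "heterospecific": est.heterospecific,
            } for est in estimates
        },
        "asymmetry": {k: {"value": v, "value_2dp": round_half_up(v)}
                      for k, v in asymmetries.items()},
        "cascade": cascade_summary,
    }

    bundle = {"barriers": barrier_df, "cascade": cascade_df,
              "constancy": constancy_out, "transitions": transitions_out,
              "vision": vision_out, "summary": summary}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        barrier_df.to_csv(out / "barriers.tsv", sep="\t", index=False)
        if cascade_df is not None:
            cascade_df.to_csv(out / "cascade.tsv", sep="\t", index=False)
        if constancy_out is not None:
            constancy_out["foragers"].to_csv(out / "constancy_foragers.tsv",
                                             sep="\t", index=False)
            constancy_out["species"].to_csv(out / "constancy_species.tsv",
                                            sep="\t", index=False)
        if transitions_out is not None:
            (out / "transitions.json").write_text(json.dumps(transitions_out, indent=2))
        if vision_out is not None:
            vision_out["loci"].to_csv(out / "vision_loci.tsv", sep="\t", index=False)
            vision_out["distances"].to_csv(out / "vision_distances.tsv", sep="\t")
            vision_out["discriminable"].to_csv(out / "vision_discriminable.tsv",
                                               sep="\t")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("report bundle written to %s", out)

    return bundle
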