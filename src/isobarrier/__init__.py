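"""isobarrier: reproductive-isolation barrier quantification for colour forms.

Library layout:

* :mod:`isobarrier.barrier_metrics` — closed-form per-barrier RI indices
  and directional asymmetry, with bootstrap intervals;
* :mod:`isobarrier.cascade` — sequential composition of barriers into
  cumulative and total RI with per-barrier contributions;
* :mod:`isobarrier.constancy` — foraging-sequence tabulation and Gegear's
  pollinator constancy index;
* :mod:`isobarrier.bee_vision` — the hymenopteran colour-hexagon model:
  quantum catches, von Kries adaptation, hexagon loci, JND discrimination;
* :mod:`isobarrier.synthetic_data` — seeded generators for every input the
  analyses consume;
* :mod:`isobarrier.io`, :mod:`isobarrier.pipeline`, :mod:`isobarrier.cli`
  — file formats, the end-to-end study pipeline and its command line.
"""

from importlib import resources

from .barrier_metrics import (BarrierEstimate, FloweringInterval, SuccessPair,
                              asymmetry, bootstrap_ci, overlap_days,
                              pairwise_ri, phenology_ri)
from .cascade import (DEFAULT_BARRIER_ORDER, BarrierCascade, CascadeResult,
                      contributions, cumulative_ri, invert_relative_success,
                      relative_success, total_ri_both_directions)
from .constancy import (ConstancyRecord, ForagingBout, TransitionTable,
                        forager_constancy, gegear_ci,
                        pollinator_success_pairs, species_ci_summary,
                        tabulate_transitions)
from .bee_vision import (HexLocus, Spectrum, VisionModel, chromatic_distance,
                         discriminable, excitation, hexagon_locus, locus_of,
                         pigment_template, quantum_catch, resample)
from .pipeline import StudyConfig, run_pipeline
from .synthetic_data import SimulationConfig, simulate_study

__version__ = "0.1.0"


def reference_study_config() -> StudyConfig:
    """The bundled Spiranthes white/pink reference-study inputs as a config."""
    root = resources.files("isobarrier") / "data" / "spiranthes"
    return StudyConfig.from_yaml(str(root / "study.yaml"))


def default_scenario_path() -> str:
    """Path to the bundled default synthetic-study scenario YAML."""
    return str(resources.files("isobarrier") / "data" / "default_scenario.yaml")
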