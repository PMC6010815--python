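# Default synthetic-study scenario: a two-colour-form orchid population
# with overlapping ~7-week flowering seasons, a highly constant honeybee-like
# species and a less constant bumblebee-like species foraging over an equal
# 20:20 array, a four-treatment hand-pollination design with overdispersed
# pollen-tube counts and ~300 scored seeds per fruit, and white/pink/
# intermediate-like reflectance spectra.  Identical to the in-code defaults
# of isobarrier.synthetic_data.SimulationConfig.
seed: 0
forms: [white, pink]
n_plants: {white: 77, pink: 40}
season_windows:
  white: [2016-07-24, 2016-08-31]
  pink: [2016-07-31, 2016-09-05]
flower_lifespan_days: 10.0
lifespan_sd_days: 2.0
availability: {white: 20, pink: 20}
species:
  - {name: apis_like, kappa: 0.95, n_foragers: 30, mean_bout_length: 10.0, n_bouts_per_forager: 1}
  - {name: bombus_like, kappa: 0.80, n_foragers: 26, mean_bout_length: 10.0, n_bouts_per_forager: 1}
n_per_cell: 30
seeds_per_fruit: 300
crossing:
  white:
    self:      {fruit_prob: 0.85, tube_mean: 146.0, tube_dispersion: 1.5, embryo_probs: [0.72, 0.12, 0.08, 0.08]}
    intraform: {fruit_prob: 0.85, tube_mean: 119.0, tube_dispersion: 1.5, embryo_probs: [0.72, 0.12, 0.08, 0.08]}
    interform: {fruit_prob: 0.37, tube_mean: 126.0, tube_dispersion: 1.5, embryo_probs: [0.46, 0.22, 0.16, 0.16]}
    control:   {fruit_prob: 0.0,  tube_mean: 0.0,   tube_dispersion: 1.5, embryo_probs: [0.0, 0.0, 0.0, 1.0]}
  pink:
    self:      {fruit_prob: 0.75, tube_mean: 42.0,  tube_dispersion: 1.5, embryo_probs: [0.51, 0.19, 0.15, 0.15]}
    intraform: {fruit_prob: 0.75, tube_mean: 84.0,  tube_dispersion: 1.5, embryo_probs: [0.65, 0.15, 0.10, 0.10]}
    interform: {fruit_prob: 0.67, tube_mean: 70.0,  tube_dispersion: 1.5, embryo_probs: [0.63, 0.15, 0.11, 0.11]}
    control:   {fruit_prob: 0.0,  tube_mean: 0.0,   tube_dispersion: 1.5, embryo_probs: [0.0, 0.0, 0.0, 1.0]}
spectra:
  white:        {base: 0.05, edges: [[408.0, 10.0, 0.70]], noise_sd: 0.005}
  pink:         {base: 0.06, edges: [[600.0, 18.0, 0.60]], bands: [[440.0, 45.0, 0.06]], noise_sd: 0.005}
  intermediate: {base: 0.05, edges: [[408.0, 10.0, 0.64]], bands: [[530.0, 55.0, -0.10]], noise_sd: 0.005}
n_spectra_per_form: 5
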