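# Methods

## Scope and model

The package quantifies reproductive isolation between two co-occurring
plant forms through a fixed sequence of barriers: phenological overlap,
pollinator foraging behaviour, pollinia–pistil interaction, fruit
production, and seed (embryo) development. Two index conventions coexist
in this literature and both are used deliberately:

* phenology is scored as `RI = 1 − S/(S+U)` (the unshared fraction of the
  focal form's flowering time, in [0, 1]);
* every other barrier is scored as `RI = 1 − 2H/(H+C)` (in [−1, 1], with
  negative values meaning heterospecific crosses outperform conspecific
  ones).

The two formulas are not mutually consistent in the full-overlap limit
(complete co-flowering gives 0 under the first and would give 0 under the
second only when H = C). We keep the mixed convention because it is how
single-barrier strengths are conventionally reported and composed in
sequential-barrier studies; the cascade uses the phenology form for stage
1 and the paired-success form thereafter.

### Day counting

Flowering intervals are inclusive of both endpoint days: a season from
24 July to 9 September spans 48 days, and two identical one-day seasons
share one day. This is the convention under which the phenology indices
of the reference inputs reproduce exactly.

### Sequential composition

Post-phenology barriers enter the cascade through their relative
heterospecific success `h = H/C`, multiplied across stages (multiplicative
independence). Two structural assumptions close the model:

* **no heterospecific success outside the co-flowering window** — there
  is no heterospecific pollen to receive when the other form is not
  flowering;
* **conspecific success identical in shared and unshared windows**,
  normalised to 1 — co-flowering is assumed not to change a form's
  conspecific performance.

With S the shared proportion of the focal form's season, total isolation
is `1 − 2·S·Πh/(S·Πh + 1)`. The test suite verifies this equals the
two-period (shared/unshared) composite formula evaluated literally, to
machine precision. Contributions `AC_i = RI[1,i] − RI[1,i−1]` telescope to
the total exactly by construction; they are order-dependent, so reports
always state the barrier order (default: life-history order). When a
study publishes a barrier's RI but not its underlying rates, the helper
`invert_relative_success` recovers `h = (1−RI)/(1+RI)`; every inversion is
logged.

### Degenerate inputs

`C = H = 0` raises an error rather than returning 0: no observed mating
events carry no information about isolation. Cascades additionally
require `C > 0` at every stage (an `h` must exist); a stage with `C = 0`
is an absolute barrier and is representable as `h = 0` only from the
heterospecific side.

## Reference-study inputs and known discrepancies

The bundled `data/spiranthes/` files encode the published field summaries
of the white/pink *Spiranthes sinensis* study: flowering dates (white
24 Jul–9 Sep, pink 31 Jul–14 Sep 2016), the pooled foraging-transition
table from the 20:20 potted-array experiment (370 white→white, 64
pink→pink, 20 each way across), mean pollen-tube counts, large-embryo
rates, and the fruit-set barrier as its published RI values (0.39/0.06;
raw rates were not published, so the pair file carries the RI and the
reader inverts it to `h`). Two reproducibility notes:

* the published white-direction pollinator RI is 0.88, while the formula
  applied to the published transition counts gives 0.897 ≈ 0.90; the
  package reports the computed value and makes no attempt to force
  agreement (the exact input behind the printed number is not
  recoverable);
* the pink-direction total recomposed from the rounded published
  summaries is 0.669 ≈ 0.67, slightly below the published 0.68, which
  evidently reflects unrounded field data. The white-direction total
  reproduces at 0.97. Neither value is tuned.

## Pollinator constancy

Transitions are consecutive moves between *distinct plants* within one
bout; repeat visits to the same plant are collapsed first and bouts are
never bridged. Gegear's `CI = (c−e)/((c+e)−2ce)` is computed per forager
over its whole observed bout set. The expected same-form proportion `e`
defaults to the forager's own visit frequencies (`e = p²+(1−p)²` with `p`
its focal-form visit share). That convention leaves CI undefined
(c = e = 1) for a forager that only ever visits one form, so for
experiments over a known floral array the focal form's availability can
be passed as `expected_share`, under which a perfectly constant forager
scores CI = 1 and availability-matched random foraging scores ≈ 0. The
simulation-based tests use the array convention (the synthetic array is
50:50); the pipeline default is the per-forager convention. Undefined CIs
are reported as missing and excluded from species means with an explicit
count. Either form may serve as focal — `e` is symmetric in `p ↔ 1−p` —
and the first label alphabetically is used for determinism.

## Colour-hexagon vision model

Spectra are resampled to a canonical 1-nm grid on 300–700 nm by linear
interpolation (no extrapolation; negative values clipped to 0 with a
warning) and integrated by the trapezoid rule. Receptor sensitivities
default to A1-pigment nomogram templates (alpha band plus a 0.26-amplitude
beta band, normalised to unit maximum) at peak wavelengths 344/436/544 nm
for the honeybee-like model and 347/436/543 nm for the bumblebee-like
model; measured sensitivity tables can be loaded from CSV instead, and
output metadata always records which receptors, illuminant and background
were used. For a UV pigment the beta band overlaps the alpha band and can
shift the curve's maximum a few nm short of the nominal peak; this is a
property of the template, not an error.

The default illuminant is an idealized open-sky daylight — normalised
black-body photon flux at 6500 K — and the default adapting background a
parametric green-foliage reflectance (dim UV/blue, a 0.14-amplitude green
bump at 550 nm over a 0.06 base, rising red edge). Both are smooth
analytic curves, not measured standards, and both are overridable by any
spectrum loaded from file; because all outputs are background-normalised
contrasts, analyses are insensitive to overall illuminant scale.

Von Kries normalisation makes loci exactly invariant to *uniform*
rescaling of stimulus and background (or of the illuminant). A
wavelength-dependent illumination change is compensated only
approximately in this full-spectrum integration model; the tests bound
the residual locus shift for a ±40% spectral tilt rather than asserting
exact invariance. The JND threshold defaults to 0.1 hexagon units
(configurable); distances in JND-scaled receptor-noise units are out of
scope — all distances are Euclidean hexagon units.

The published chromatic distances between the colour forms depend on
unpublished measured spectra and unspecified viewing conditions, so they
are not reproducible from first principles. What the package asserts
instead is structural: the background maps to the origin, loci stay
inside the unit hexagon, and synthetic white/pink/intermediate spectra
reproduce the qualitative result — white vs pink well above the 0.1-unit
threshold, white vs intermediate below it, with the same ordering under
both bee models.

## Synthetic-data generator

The generator emulates the study's structure, not any particular field
season. Defaults: 77 white and 40 pink plants; per-plant first-flower
dates uniform within a form-level window, scape flowering spans normal
around 10 days (SD 2, floored at 1); a highly constant honeybee-like
species (stay-probability κ = 0.95, 30 foragers) and a less constant
bumblebee-like species (κ = 0.80, 26 foragers) foraging over an equal
20:20 array with Poisson bout lengths around 10 visits; a four-treatment
crossing design (self, intraform, interform, unmanipulated control with
fruit probability 0 — the species sets no fruit autogamously) with 30
flowers per cell, Bernoulli fruit set, negative-binomial pollen-tube
counts (dispersion k = 1.5, matching the published SDs ≈ means, i.e.
strong overdispersion), and multinomial embryo categories
(large/small/aborted/empty) over ~300 scored seeds per fruit. Cell means
are set near the published treatment means so that the default scenario's
expected barrier strengths bracket the reference values.

Floral reflectance is parametric — a base level plus Gaussian bands and
logistic edges, with Gaussian noise (SD 0.005) clipped to [0, 1]: the
white-like form is bright above a 408-nm cut-on and UV-dark, the
pink/magenta-like form is dark across the bee-visual range except a weak
blue reflection and a steep 600-nm red edge, and the intermediate is a
white-like curve with a shallow green-absorbing dip.

The forager is a two-state Markov chain: stay on the current form with
probability κ, otherwise choose a form by availability (so a "switch"
draw can land on the same form). Its stationary occupancy equals
availability, giving the closed-form pollinator-stage relative success
`h = (1−a)(1−κ)/(κ + (1−κ)a)` — `(1−κ)/(1+κ)` at equal availability —
which the parameter-recovery tests exploit: synthetic studies with known
κ and known per-stage `h` (100 observations per crossing cell, 200
replicates, phenology held fixed) recover the generating total RI with
bias well under 0.02, and mean CI is strictly increasing in κ with ≈ 0 at
the availability-random setting.

What the generator does **not** emulate: spatial foraging structure
(plants have no positions), visit durations, weather- or date-dependent
visitation, pollinarium depletion, inheritance of the intermediate form,
and any correlation between barriers beyond the shared seasonal window.
Passing tests therefore certify the estimators and their composition
under the stated stochastic structure, not the field behaviour of real
bees.

All generators draw from one `numpy.random.Generator` in a fixed order,
so a scenario seed reproduces every file byte-for-byte.

## Numerical choices

* Two-decimal report values use round-half-away-from-zero (the convention
  of printed field tables); full precision is kept internally and in all
  serialised numerics — rounding happens only in `*_2dp` report fields.
* Bootstrap intervals are percentile intervals over B = 2000 resamples by
  default, resampling the conspecific and heterospecific observation
  vectors independently; degenerate resamples (C = H = 0) are skipped
  with a logged count. Intervals are reproducible under a fixed seed.
* Asymmetries are computed on unrounded indices and rounded only for
  reporting.
* Problem sizes in the test suite (e.g. 200 recovery replicates, 100
  bootstrap-coverage replicates at B = 2000) were chosen to keep
  Monte-Carlo error comfortably below the tolerances they check.

## Known limitations

* Contributions are order-dependent by construction; the default
  life-history order is a modelling commitment, not a mathematical
  necessity.
* The cascade treats stages as independent given the co-flowering window;
  correlated barriers (e.g. pollinator behaviour that also affects pollen
  load quality) are not modelled.
* The vision model is chromatic only — achromatic (green-receptor)
  contrast, which bees use at small visual angles, is out of scope.
* Published hexagon distances cannot be recovered without the original
  measured spectra; only qualitative structure is checked.
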