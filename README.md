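# isobarrier

Quantifying reproductive isolation (RI) between co-occurring plant forms —
here, the white and pink colour forms of the *Spiranthes sinensis* orchid
complex — from the kinds of data a pollination-biology field study
produces: flowering dates, pollinator foraging sequences, hand-pollination
crossing outcomes, and floral reflectance spectra.

The package computes per-barrier isolation indices, composes them
sequentially into total isolation with per-barrier contributions, scores
pollinator constancy, and models whether bees can discriminate the colour
forms. A seeded synthetic-data generator emulates every input so the whole
pipeline is testable end to end without field data.

## The indices

**Phenological isolation** for a focal form, from shared (S) and unshared
(U) flowering time (inclusive day counts):

    RI = 1 − S/(S+U)

**Paired-success isolation** for every other barrier, from a conspecific
(intraform) success measure C and the matching heterospecific (interform)
measure H — foraging transitions, mean pollen tubes entering the ovary,
fruit-set rates, large-embryo rates:

    RI = 1 − 2·H/(H+C)        ∈ [−1, 1]

**Sequential composition.** Barriers act in life-history order (phenology →
pollinator foraging → pollinia–pistil → fruit set → seed development).
Each post-phenology stage enters through its relative heterospecific
success h = H/C; these multiply across stages, heterospecific mating is
confined to the co-flowering window, and the cumulative isolation through
stage *i* is

    RI[1,i] = 1 − 2·S·Π h_j / (S·Π h_j + 1),   RI[1,1] = U

Absolute contributions AC_i = RI[1,i] − RI[1,i−1] telescope exactly to the
total; relative contributions are RC_i = AC_i / RI_total. A barrier's
directional asymmetry is |RI_white − RI_pink|.

**Pollinator constancy** per forager uses Gegear's index
CI = (c − e)/((c + e) − 2ce) with e = p² + (1−p)², from the proportion of
same-form transitions c and the focal-form visit share p (or the floral
array's availability, for experiments with a known array).

**Bee colour vision** follows the hexagon model for trichromatic
hymenopterans: von Kries background-normalised quantum catches per
receptor, excitations E = P/(P+1), hexagon coordinates
x = (√3/2)(E_g − E_uv), y = E_b − (E_uv + E_g)/2, Euclidean chromatic
distance in hexagon units, and a just-noticeable-difference threshold
(default 0.1 units) for discriminability.

## Worked example

The package ships the published field summaries of the white/pink study as
ordinary input files. Running the pipeline on them:

```python
import isobarrier as ib

bundle = ib.run_pipeline(ib.reference_study_config())
df = bundle["cascade"]
print(df[df.maternal_form == "white"][
    ["barrier", "cumulative_ri", "abs_contribution", "rel_contribution"]
].round(4).to_string(index=False))
```

prints the white-maternal cascade:

```
         barrier  cumulative_ri  abs_contribution  rel_contribution
       phenology         0.1458            0.1458            0.1498
      pollinator         0.9117            0.7659            0.7868
     pollen_tube         0.9070           -0.0047           -0.0049
       fruit_set         0.9581            0.0511            0.0525
seed_development         0.9735            0.0154            0.0158
```

Reading: the two forms co-flower for 41 of the white form's 48 flowering
days, so phenology alone gives RI = 0.15. Selective foraging by the bee
guilds is by far the strongest barrier (it alone lifts cumulative
isolation to 0.91, contributing 0.77 of the total). Pollen-tube growth is
slightly *anti*-isolating in this direction (negative contribution), and
fruit set and seed development add the rest, for a total RI of 0.97. The
pink-maternal direction composes to 0.67 — isolation is strongly
asymmetric, with the white form much better protected.

The same analyses are available from the shell:

```sh
isobarrier simulate --seed 3 --out sim/          # synthetic study inputs
isobarrier run --config study.yaml --out report/ # full pipeline
isobarrier constancy --foraging sim/foraging.csv
isobarrier vision --spectra sim/spectra.csv --model honeybee
```

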