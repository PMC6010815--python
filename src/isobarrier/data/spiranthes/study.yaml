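# Reference study inputs for the Spiranthes sinensis white/pink colour-form
# system (Yulong Mountain, Yunnan): published field-summary values encoded in
# the package's ordinary input formats.
#
# flowering.csv      form-level first/last flowering dates, 2016 season
# transitions.csv    pooled plant-to-plant foraging transitions from the
#                    20x20 potted-array choice experiment
# barrier_pairs.csv  post-pollination success pairs: mean pollen tubes
#                    entering the ovary, large-embryo rates (%), and the
#                    fruit-set barrier as its published RI (no raw rates
#                    were published; inverted to h = (1-RI)/(1+RI))
forms: [white, pink]
phenology: flowering.csv
transitions: transitions.csv
barrier_pairs: barrier_pairs.csv
barrier_order: [pollinator, pollen_tube, fruit_set, seed_development]
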