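barrier,maternal_form,conspecific,heterospecific,ri,n
pollen_tube,white,118.93,125.62,,59
pollen_tube,pink,83.95,69.75,,39
fruit_set,white,,,0.39,
fruit_set,pink,,,0.06,
seed_development,white,72.42,45.51,,66
seed_development,pink,65.48,63.35,,58
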