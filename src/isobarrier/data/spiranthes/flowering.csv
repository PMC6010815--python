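form,first_day,last_day
white,2016-07-24,2016-09-09
pink,2016-07-31,2016-09-14
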