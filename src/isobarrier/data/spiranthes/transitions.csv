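from_form,to_form,count
white,white,370
white,pink,20
pink,white,20
pink,pink,64
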