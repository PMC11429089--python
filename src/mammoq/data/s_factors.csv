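# EUREF/Dance spectral correction factor s per target/filter combination.
target_filter,s
Mo/Mo,1.000
Mo/Rh,1.017
Rh/Rh,1.061
Rh/Al,1.044
W/Rh,1.042
W/Ag,1.042
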