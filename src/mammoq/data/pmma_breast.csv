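# EUREF equivalence between PMMA slab thickness and the typical breast of
# equal absorption: 45 mm PMMA ~ 53 mm breast.
pmma_mm,breast_mm
20,21
30,32
40,45
45,53
50,60
60,75
70,90
80,103
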