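# EUREF/Dance glandularity correction factor c for the standard breast of the
# 50-64 age group, vs breast thickness (cm) and HVL (mm Al). The HVL dependence
# of c is weak over the mammographic band and is neglected (columns identical).
thickness_cm,0.30,0.35,0.40,0.45,0.50,0.55,0.60
2.0,0.885,0.885,0.885,0.885,0.885,0.885,0.885
3.0,0.925,0.925,0.925,0.925,0.925,0.925,0.925
4.0,0.985,0.985,0.985,0.985,0.985,0.985,0.985
4.5,1.000,1.000,1.000,1.000,1.000,1.000,1.000
5.0,1.021,1.021,1.021,1.021,1.021,1.021,1.021
6.0,1.063,1.063,1.063,1.063,1.063,1.063,1.063
7.0,1.097,1.097,1.097,1.097,1.097,1.097,1.097
8.0,1.123,1.123,1.123,1.123,1.123,1.123,1.123
9.0,1.144,1.144,1.144,1.144,1.144,1.144,1.144
10.0,1.160,1.160,1.160,1.160,1.160,1.160,1.160
11.0,1.173,1.173,1.173,1.173,1.173,1.173,1.173
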