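# EUREF/Dance incident-air-kerma -> glandular-dose conversion factor g (mGy/mGy)
# for a 50%-glandularity breast, vs breast thickness (cm) and HVL (mm Al).
# Values reconstructed from the published EUREF protocol tables.
thickness_cm,0.30,0.35,0.40,0.45,0.50,0.55,0.60
2.0,0.390,0.433,0.473,0.509,0.543,0.573,0.587
3.0,0.274,0.310,0.342,0.374,0.406,0.437,0.466
4.0,0.207,0.235,0.261,0.289,0.318,0.346,0.374
4.5,0.183,0.208,0.232,0.258,0.285,0.311,0.339
5.0,0.164,0.187,0.209,0.232,0.258,0.287,0.310
6.0,0.135,0.154,0.172,0.192,0.214,0.236,0.261
7.0,0.114,0.130,0.145,0.163,0.177,0.202,0.224
8.0,0.098,0.112,0.126,0.140,0.154,0.175,0.195
9.0,0.0859,0.0981,0.1106,0.1228,0.1357,0.1543,0.1723
10.0,0.0763,0.0873,0.0986,0.1096,0.1212,0.1382,0.1547
11.0,0.0687,0.0786,0.0887,0.0988,0.1093,0.1249,0.1400
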