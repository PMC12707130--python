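# Asymptotic upper critical values for Watson's U^2 statistic
# (two-sample test for homogeneity on the circle).
# Source: Stephens (1965) "The goodness-of-fit statistic Vn", and standard
# circular-statistics tables (e.g. Zar, Biostatistical Analysis, App. B).
alpha,critical
0.10,0.152
0.05,0.187
0.01,0.268
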