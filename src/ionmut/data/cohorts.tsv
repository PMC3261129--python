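let	dose_gy	n_m1	n_m2	n_mutants
22.5	250	2024	11662	5
22.5	450	1710	16103	5
30.0	400	3056	29595	23
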