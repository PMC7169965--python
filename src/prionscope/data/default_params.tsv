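# Default scoring parameters for the prion-like composition LLR model.
# f_P = prion-state amino-acid frequencies, modeled on the composition of
#       experimentally characterised yeast prion-forming domains (N/Q-rich,
#       S/G/Y-enriched, depleted in hydrophobics and charge).
# f_B = background frequencies (Swiss-Prot average composition).
# Tables are renormalised on load with a 1e-6 pseudocount floor.
log_base	2.718281828459045
core_length	60
prion_run	100
background_run	500
f_P	A	0.050
f_P	C	0.005
f_P	D	0.020
f_P	E	0.020
f_P	F	0.030
f_P	G	0.090
f_P	H	0.015
f_P	I	0.020
f_P	K	0.025
f_P	L	0.030
f_P	M	0.015
f_P	N	0.210
f_P	P	0.050
f_P	Q	0.180
f_P	R	0.020
f_P	S	0.105
f_P	T	0.040
f_P	V	0.025
f_P	W	0.005
f_P	Y	0.045
f_B	A	0.0825
f_B	C	0.0138
f_B	D	0.0545
f_B	E	0.0675
f_B	F	0.0386
f_B	G	0.0707
f_B	H	0.0227
f_B	I	0.0596
f_B	K	0.0584
f_B	L	0.0966
f_B	M	0.0242
f_B	N	0.0406
f_B	P	0.0470
f_B	Q	0.0393
f_B	R	0.0553
f_B	S	0.0656
f_B	T	0.0534
f_B	V	0.0687
f_B	W	0.0108
f_B	Y	0.0292
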