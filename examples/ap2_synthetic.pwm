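# name=ap2_synthetic
# low_threshold=30
A	C	G	T
0.305	0.566	3.449	0.565
0.186	3.741	0.493	0.244
0.327	3.699	0.449	0.321
0.196	3.463	0.181	0.27
3.808	0.24	0.121	0.156
0.447	0.167	3.934	0.584
0.573	0.432	3.779	0.165
0.096	0.578	3.581	0.069
0.371	3.926	0.365	0.547
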