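# name=p53_synthetic
# low_threshold=50
A	C	G	T
4.896	0.21	0.572	0.065
0.422	5.018	0.132	0.039
4.766	0.462	0.395	0.105
0.304	0.47	0.297	4.618
0.68	0.48	4.601	0.132
0.243	4.608	0.626	0.545
0.224	4.905	0.331	0.488
0.075	4.559	0.142	0.622
0.478	0.597	4.494	0.286
0.363	0.417	5.066	0.308
0.627	0.431	4.55	0.35
0.487	4.797	0.367	0.152
4.824	0.027	0.493	0.321
0.631	0.587	0.271	4.916
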