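position	A	C	G	T	IC
-3	0	0	2	2	1.000000
-2	1	0	2	1	0.500000
-1	2	0	0	2	1.000000
0	0	0	4	0	2.000000
1	0	0	0	4	2.000000
2	0	2	1	1	0.500000
3	2	0	2	0	1.000000
4	2	0	1	1	0.500000
5	0	2	2	0	1.000000
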