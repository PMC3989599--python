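position	A	C	G	T	IC
-6	2	1	0	1	0.500000
-5	1	3	0	0	1.188722
-4	2	1	1	0	0.500000
-3	1	3	0	0	1.188722
-2	4	0	0	0	2.000000
-1	0	0	4	0	2.000000
0	1	1	1	1	0.000000
1	1	1	0	2	0.500000
2	1	0	2	1	0.500000
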