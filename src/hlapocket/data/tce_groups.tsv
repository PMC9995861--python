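#provenance=hlapocket fixture v1; printed residue positions transcribed from the study tables, remaining positions synthetic (see docs/methods.md)
#coordinate=mature
allele	group
02:01	3
02:02	3
04:01	3
04:02	3
17:01	1
23:01	3
30:01	3
39:01	3
40:01	3
49:01	3
55:01	3
106:01	3
126:01	3
133:01	3
138:01	3
535:01	3
907:01	3
01:01	2
03:01	2
05:01	3
06:01	3
09:01	1
10:01	1
11:01	3
13:01	3
14:01	2
15:01	3
16:01	3
18:01	3
19:01	3
20:01	3
21:01	3
29:01	3
35:01	3
36:01	3
45:01	2
85:01	3
90:01	3
100:01	3
104:01	3
131:01	3
350:01	3
417:01	3
519:01	3
105:01	3
99:99	3
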