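#provenance=hlapocket fixture v1; printed residue positions transcribed from the study tables, remaining positions synthetic (see docs/methods.md)
#coordinate=mature
allele	class
02:01	A
02:02	A
04:01	A
04:02	A
17:01	A
23:01	A
30:01	A
39:01	A
40:01	A
49:01	A
55:01	A
106:01	A
126:01	A
133:01	A
138:01	A
535:01	A
907:01	A
01:01	G
03:01	G
05:01	G
06:01	G
09:01	G
10:01	G
11:01	G
13:01	G
14:01	G
15:01	G
16:01	G
18:01	G
19:01	G
20:01	G
21:01	G
29:01	G
35:01	G
36:01	G
45:01	G
85:01	G
90:01	G
100:01	G
104:01	G
131:01	G
350:01	G
417:01	G
519:01	G
105:01	G
99:99	G
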