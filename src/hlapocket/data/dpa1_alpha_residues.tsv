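#provenance=hlapocket fixture v1; printed residue positions transcribed from the study tables, remaining positions synthetic (see docs/methods.md)
#coordinate=mature
allele	chain	position	residue
01:03	alpha	9	F
01:03	alpha	11	A
01:03	alpha	22	A
01:03	alpha	24	F
01:03	alpha	31	M
01:03	alpha	32	Q
01:03	alpha	43	K
01:03	alpha	52	R
01:03	alpha	53	S
01:03	alpha	54	F
01:03	alpha	55	R
01:03	alpha	58	E
01:03	alpha	62	N
01:03	alpha	65	I
01:03	alpha	66	I
01:03	alpha	68	A
01:03	alpha	69	N
01:03	alpha	72	L
01:03	alpha	73	M
01:03	alpha	76	M
02:01	alpha	9	F
02:01	alpha	11	M
02:01	alpha	22	A
02:01	alpha	24	F
02:01	alpha	31	Q
02:01	alpha	32	Q
02:01	alpha	43	K
02:01	alpha	52	R
02:01	alpha	53	S
02:01	alpha	54	F
02:01	alpha	55	R
02:01	alpha	58	E
02:01	alpha	62	N
02:01	alpha	65	I
02:01	alpha	66	V
02:01	alpha	68	A
02:01	alpha	69	N
02:01	alpha	72	L
02:01	alpha	73	M
02:01	alpha	76	M
02:02	alpha	9	F
02:02	alpha	11	M
02:02	alpha	22	A
02:02	alpha	24	F
02:02	alpha	31	Q
02:02	alpha	32	Q
02:02	alpha	43	K
02:02	alpha	52	R
02:02	alpha	53	S
02:02	alpha	54	F
02:02	alpha	55	R
02:02	alpha	58	E
02:02	alpha	62	N
02:02	alpha	65	I
02:02	alpha	66	V
02:02	alpha	68	A
02:02	alpha	69	N
02:02	alpha	72	L
02:02	alpha	73	M
02:02	alpha	76	M
03:01	alpha	9	F
03:01	alpha	11	M
03:01	alpha	22	A
03:01	alpha	24	F
03:01	alpha	31	Q
03:01	alpha	32	Q
03:01	alpha	43	K
03:01	alpha	52	R
03:01	alpha	53	S
03:01	alpha	54	F
03:01	alpha	55	R
03:01	alpha	58	E
03:01	alpha	62	N
03:01	alpha	65	I
03:01	alpha	66	V
03:01	alpha	68	A
03:01	alpha	69	N
03:01	alpha	72	L
03:01	alpha	73	M
03:01	alpha	76	M
99:99	alpha	9	F
99:99	alpha	11	M
99:99	alpha	22	A
99:99	alpha	24	F
99:99	alpha	31	Q
99:99	alpha	32	Q
99:99	alpha	43	K
99:99	alpha	52	R
99:99	alpha	53	S
99:99	alpha	54	F
99:99	alpha	55	R
99:99	alpha	58	E
99:99	alpha	62	N
99:99	alpha	65	I
99:99	alpha	66	V
99:99	alpha	68	A
99:99	alpha	69	N
99:99	alpha	72	L
99:99	alpha	73	M
99:99	alpha	76	M
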