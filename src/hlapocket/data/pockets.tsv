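#provenance=hlapocket fixture v1; DP pocket membership (4-A neighborhood)
#coordinate=mature
pocket	chain	positions
P1	alpha	24,31,32,43,52,53,54,55
P1	beta	80,83,84
P2	alpha	9
P2	beta	76,79,80
P3	alpha	22,54,58
P3	beta	
P4	alpha	9,62
P4	beta	13,24,26,68,69,72,76
P5	alpha	
P5	beta	69
P6	alpha	11,62,65,66
P6	beta	11,13,26,28
P7	alpha	65,69
P7	beta	26,28,45,59,65,68,69
P8	alpha	65,68,69
P8	beta	
P9	alpha	69,72,73,76
P9	beta	9,28,35,36,55,59
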