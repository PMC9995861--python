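#provenance=hlapocket fixture v1; printed residue positions transcribed from the study tables, remaining positions synthetic (see docs/methods.md)
#coordinate=mature
allele	sequence
02:01	VHGVDEDLEMGGPMAA
02:02	VHGVEEDLEMGGPMAC
04:01	VYGAAAEIKMGGPMAD
04:02	VHGVDEDIKMGGPMAE
17:01	LHLVDEDLEMDEAVAF
23:01	VHGVAAEIKMGGPMAG
30:01	LHLVEEDLEMDEAVAH
39:01	VYGAAAEIKMGGPMAI
40:01	VYGAAAEIKMVGPMAK
49:01	VYGADEDIKMGGPMAL
55:01	LHLVAAELEMDEAVAM
106:01	VHGVEEDLEIDEAVAN
126:01	VYGAAAEIKMGGPMAP
133:01	LYLAAAELEIDEAVAQ
138:01	VHGVAAEIKMGGPMAR
535:01	VHGVEEDLEIDEAVAS
907:01	LYLAAAELRMDEAVAT
01:01	VYGAAAEIKVDEAVAV
03:01	LHLVDEDIKVDEAVAW
05:01	VHGVEEDIKMDEAVAY
06:01	LHLVDEDLEMDEAVCA
09:01	LHLVDEDLEVDEAVCC
10:01	LHLVDEDLEVDEAVCD
11:01	LYLAAAELRMDEAVCE
13:01	LYLAAAELEIDEAVCF
14:01	LHLVDEDIKVDEAVCG
15:01	VYGAAAELRMVGPMCH
16:01	VHGVDEDLEMDEAVCI
18:01	VHGVDEDIKMVGPMCK
19:01	VHGVEEDLEIDEAVCL
20:01	LHLVDEDIKMDEAVCM
21:01	LHLVEEDLEMDEAVCN
29:01	LHLVDEDLEVDEAVCP
35:01	LHLVDEDIKVDEAVCQ
36:01	LHLVEEDIKMDEAVCR
45:01	LHLVDEDIKVDEAVCS
85:01	LYLAAAEIKMDEAVCT
90:01	VYGAAAEIKVDEAVCV
100:01	VHGVEEDIKMGGPMCW
104:01	LHLVDEDIKVDEAVCY
131:01	LHLVDEDLEMDEAVDA
350:01	VYGAAAEIKMGGPMDC
417:01	VYGAAAEIKVDEAVDD
519:01	LYLAAAELEIDEAVDE
105:01	LHLVDEDIKVDEAVDF
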