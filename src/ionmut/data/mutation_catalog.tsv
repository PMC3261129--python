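let	dose_gy	allele_id	gene	type	size	change	position
22.5	250	C-27-gl1	GL1	BS		G>A	Chr.5: 10,363,437
22.5	250	C-45-hy1	HY4	Del	2		Chr.4: 5,724,273-74
22.5	250	C-48-amp1	AMP1	BS		A>T	Chr.3: 20,255,432
22.5	250	C-55-hy1	HY4	Del	3		Chr.4: 5,725,528-30
22.5	250	C-142-hy1	HY3	Del	1		Chr.2: 8,141,902
22.5	250	C-162-gl1	TTG1	Del	51		Chr.5: 8,371,718-68
22.5	450	C(450)-100-gl1	TTG1	Del	1		Chr.5: 8,372,723
22.5	450	C(450)-124-hy1	HY3	BS		G>T	Chr.2: 8,143,452
22.5	450	C(450)-135-hy1	HY1	Del	36		Chr.2: 11,342,207-42
22.5	450	C(450)-139-pid1	PID1	RTL
22.5	450	C(450)-150-pid1	PID1	Ins	1		Chr.2: 14,590,504
22.5	450	C(450)-154-hy1	HY4	Del	32335		Chr.4: 5,697,598-730,031
30.0	400	C30-8-gl1		NM
30.0	400	C30-9-gl2	GL2	Del	1		Chr.1: 30,038,621
30.0	400	C30-39-hy1	HY2	Del	5		Chr.3: 2,805,174-78
30.0	400	C30-73-gl1	TTG1	CR
30.0	400	C30-74-hy1	HY4	Del	2		Chr.4: 5,725,263-64
30.0	400	C30-106-gl1	GL2	Del	1		Chr.1: 30,039,697
30.0	400	C30-108-hy1	HY4	RTL
30.0	400	C30-148-amp1	AMP1	Del	1		Chr.3: 20,257,195
30.0	400	C30-155-hy1	HY2	Del	4		Chr.3: 2,804,929-32
30.0	400	C30-252-gl1	GL2	BS		C>A	Chr.1: 30,040,486
30.0	400	C30-273-var1	VAR2	Del	23		Chr.2: 13,175,250-72
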