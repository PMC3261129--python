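allele_id	left_flank	del_prefix	del_suffix	right_flank	declared_size	truth_mh
C-162-gl1	AGTGGTCTT	CTTCGC	CTCCTT	AGAGTT	51	3
C(450)-135-hy1	AAAACTCA	CAA	CAGTTCA	AGAG	36	3
C(450)-154-hy1	AACTAA	ACCGTA	GGTATG	GTTCA	32335	0
C30-273-var1	GGTTTGT	TCCTT	GTCTGGT	GGTGG	23	2
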