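allele_id	wt_seq	mut_seq	truth_type	truth_size	truth_mh_markup
C-45-hy1	TCTGGTTCTGTATCTGGTTGTGGT	TCTGGTTCTGTCTGGTTGTGGT	Del	2	1
C-55-hy1	GGCCGGACTGGATATCCGTTGGTC	GGCCGGACTGATCCGTTGGTC	Del	3	0
C-142-hy1	GATGCGATTCACTCGCTCCAGCT	GATGCGATTCATCGCTCCAGCT	Del	1	0
C(450)-100-gl1	CATGGATAATTCAGCTCCAGATT	CATGGATAATTAGCTCCAGATT	Del	1	0
C(450)-150-pid1	AACTCCGTTCACCGCGAC	AACTCCGTTTCACCGCGAC	Ins	1	0
C30-9-gl2	TGCAGGCTATTCAAAGAGACA	TGCAGGCTATCAAAGAGACA	Del	1	1
C30-39-hy1	CATTGAACAGGAAATCCCTTAGC	CATTGAACATCCCTTAGC	Del	5	1
C30-74-hy1	TTCTTTCTCCACACTTGC	TTCTTTCTACACTTGC	Del	2	0
C30-106-gl1	AGTGTACTTCGTGAGAAG	AGTGTACTCGTGAGAAG	Del	1	1
C30-148-amp1	CTTGGGAAGAGGAGCAATT	CTTGGGAAGGGAGCAATT	Del	1	0
C30-155-hy1	TGACATGGCGAGCACAAAAGGT	TGACATGGCACAAAAGGT	Del	4	1
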