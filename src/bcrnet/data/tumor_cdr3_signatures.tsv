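patient_no	cdr3_nt	fraction
419	TGTCAGCAAAGTTACAGTATTCCTCGGACGTTC	86.2%
419	TGTCAGCAAAGTTACAGTATTCCTCGGACCTTC	7.9%
457	CAGCAGTATGGTAGCTCACCGGCGACG	92.5%
457	CAGCAGTATGGTAGCTCACCGGCGACC	6.4%
548	TGTCAGCAGATTGATACCTGGCCTCGAACCTTC	97.3%
548	TGTCTGCAGCATAATAGATACCCGCTCACTTTC	0.6%
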