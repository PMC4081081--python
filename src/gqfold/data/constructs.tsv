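name	sequence	notes
cMyc	TGGCGACGGCAGCGAGGCGGGTGGGGAGGGTGGG	3'Cy3
133	TGGCGACGGCAGCGAGGCGGGTGGGTTTGGGTTTGGG	3'Cy3
144	TGGCGACGGCAGCGAGGCGGGTGGGTTTTGGGTTTTGGG	3'Cy3
155	TGGCGACGGCAGCGAGGCGGGTGGGTTTTTGGGTTTTTGGG	3'Cy3
177	TGGCGACGGCAGCGAGGCGGGTGGGTTTTTTTGGGTTTTTTTGGG	3'Cy3
199	TGGCGACGGCAGCGAGGCGGGTGGGTTTTTTTTTGGGTTTTTTTTTGGG	3'Cy3
233	TGGCGACGGCAGCGAGGCGGGTTGGGTTTGGGTTTGGG	3'Cy3
333	TGGCGACGGCAGCGAGGCGGGTTTGGGTTTGGGTTTGGG	3'Cy3;alias=TTT
433	TGGCGACGGCAGCGAGGCGGGTTTTGGGTTTGGGTTTGGG	3'Cy3
533	TGGCGACGGCAGCGAGGCGGGTTTTTGGGTTTGGGTTTGGG	3'Cy3
TTA	TGGCGACGGCAGCGAGGCGGGTTAGGGTTAGGGTTAGGG	3'Cy3
TAA	TGGCGACGGCAGCGAGGCGGGTAAGGGTAAGGGTAAGGG	3'Cy3
AAA	TGGCGACGGCAGCGAGGCGGGAAAGGGAAAGGGAAAGGG	3'Cy3
T25	TGGCGACGGCAGCGAGGCTTTTTTTTTTTTTTTTTTTTTTTTT	3'Cy3;non-GQ control
Amino18nt	GCCTCGCTGCCGTCGCCA	iamino@7;3'Bio;stem complement annealed to all 3'Cy3 sequences
313	TGGCGACGGCAGCGAGGCGGGTTTGGGTGGGTTTGGG	
331	TGGCGACGGCAGCGAGGCGGGTTTGGGTTTGGGTGGG	
515	TGGCGACGGCAGCGAGGCGGGTTTTTGGGTGGGTTTTTGGG	
551	TGGCGACGGCAGCGAGGCGGGTTTTTGGGTTTTTGGGTGGG	
717	TGGCGACGGCAGCGAGGCGGGTTTTTTTGGGTGGGTTTTTTTGGG	
771	TGGCGACGGCAGCGAGGCGGGTTTTTTTGGGTTTTTTTGGGTGGG	
919	TGGCGACGGCAGCGAGGCGGGTTTTTTTTTGGGTGGGTTTTTTTTTGGG	
991	TGGCGACGGCAGCGAGGCGGGTTTTTTTTTGGGTTTTTTTTTGGGTGGG	
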