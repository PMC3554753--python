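mirna_id	sequence	length	tpm_10DAF	tpm_15DAF	tpm_21DAF	tpm_27DAF	tpm_35DAF	evidence
miRn1-5p	CGGCGATGTGGGGGAGGCGCG	21	5.47	0	0	0	0	*
miRn2-5p	AACACACCGGATTCGAATCTTTT	23	0.49	0	0	0	0	*
miRn3-5p	TCGACCACGTCGAAGAGGCTCA	22	0	0.45	0	0	0	*
miRn4-5p	TCAACTTCGTTTCGTGAGGCA	21	0	0	0.79	0	0	*
miRn5-5p	CGGTGACAGAAGAGAGTGAGCAC	23	0	0	0	0.43	0.47	*
miRn6-5p	TTAGTCTACGTTTCATCTCTC	21	0	0	0	1.2	0	*
miRn7-3p	TCTGCTAATGGTGGTCAGGAC	21	0	0	0	1.03	1.59	*
miRn8-3p	TAGGATGAGAGTTGCATGGTT	21	0	0	4.22	0	0	*
miRn9-5p	AAGGGGCGCTTACTGAGAGTTCT	23	0	0.38	0	0	0	*
miRn10-5p	TCTTATTGGGTCGTGCCTAGGC	22	1.4	0.83	0	0	0	*
miRn11-5p	TGTGTAGCCACATTGTAAGGG	21	0.35	0	0	0	1.13	*
miRn12-5p	TGGCCTGTAGTTAGTAGAGGG	21	0	0	0.53	0	0	*
miRn13-3p	TCAGCACGGATACATTATTTT	21	0.42	0	0	0	0	*
miRn14-3p	TGGGAATATTCTTTATCTGTT	21	0	0.83	0	0	0	*
miRn15-5p	TAAATGGAGAGAACGAAAGAG	21	0	0	4.39	0	0	*
miRn16-3p	TCGGACTCTCGGCGGCGCTCG	21	0	0	0	0	0.84	*
miRn17-5p	TCTTTCACATGGTATTAGAGCTG	23	0	0.98	1.05	0	0	*
miRn18-3p	TAGATATATATCTAGGATTGGAT	23	0.77	1.43	0	0.94	1.31	*, T
miRn19-3p	TAACAAAGGACAACAGACTGA	21	1.89	0.98	0.88	0.86	1.59	*, T
miRn20-3p	CTTTGAGTAGGGTCTAAACAGAG	23	7.16	12.86	12.83	7.38	9.38	*, T
miRn21-5p	CAGGCAGAGCATGAAGAGCAT	21	0	1.13	1.05	1.29	0	*, T
miRn22-3p	TACATTTGGAACCAGAGGGAC	21	3.65	4.51	14.24	19.49	17.17	*, T
miRn23-5p	TGAGGACAAGAGCTGATTCGG	21	6.46	3.84	9.84	3.18	1.03	T
miRn24-3p	TTTGAACTTGATATTTGGTGG	21	1.75	1.96	1.32	1.03	1.22	T
miRn25-3p	TACGAGAGATGGGAAAAGACAAC	23	1.12	2.41	1.32	1.29	0.66	T
miRn26-5p	TTTCTTGACTCGGGATGACTAG	22	1.33	1.2	0	0.69	0.75	T
miRn27-5p	TCGGGATATGTGGTATTGCGGTT	23	0.84	0	1.05	1.29	0	T
miRn28-5p	CACGGAATGGAAGAGCGAGAC	21	0.7	1.13	0	0	4.03	T
miRn29-5p	ACCCCCCTTTGCCGGCGCGCGC	22	0.49	0.75	0	0.6	0.47	T
miRn30-5p	TGAAAAGTTGGGAATTTGGAG	21	0.77	0	0.62	0.69	0.47	T
miRn31-5p	TGGGTTTGGGTGGTGGTGGTGCA	23	2.67	3.01	0.97	0	0.66	T
miRn32-5p	TAGATGGCTGATCTGGTGTGG	21	1.68	0	2.72	2.66	4.03	T
miRn33-3p	TGAGATTGGTTTATTTTGGGA	21	1.05	1.88	1.49	1.72	0	T
miRn34-5p	TTCGTAAGTGGAACCGCACGG	21	0.42	0	0	3.26	0.84	T
miRn35-3p	TCAGGAGCAGAAGATGAGGGAG	22	2.39	5.11	4.57	5.41	4.5	T
miRn36-5p	TCTCACTTTGGACTAGGTATT	21	4.35	8.12	10.81	11.59	11.63	T
miRn37-3p	TTGGTAAGGCGAAAATTGGCAT	22	1.82	1.13	1.49	1.89	1.78	T
miRn38-3p	TTGGGGAACGCGCCGATCGTC	21	0.63	0	3.16	1.97	2.06	T
miRn39-5p	TGCTCCGGATATTATGGCATG	21	4.63	5.11	2.81	3.61	6.29	T
miRn40-3p	TCTGAGACAGCGTAGACAGTT	21	1.75	1.73	1.58	0	0	T
miRn41-3p	TGCGAAGTAGAGATGCCGACT	21	0	1.73	1.14	0.94	0	T
miRn42-5p	ATCTCGATGGTGATTGTTGCT	21	0	1.43	0	0.6	0.47	T
miRn43-3p	TTTTGGGAGGATGGCAAATAG	21	0	0.83	0.79	0.77	0	T
miRn44-3p	TCGATGCAGTCCTCGATGTCG	21	0	0.53	0	0.52	1.31	T
miRn45-5p	GCTGGAGTAGCTCAGATGGT	20	93.06	175.82	363.22	317.49	596.71	T
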