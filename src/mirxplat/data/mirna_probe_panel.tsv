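# Twelve-assay mouse miRNA probe panel: mature miRNA sequences (RNA) with the
# corresponding Agilent-style and Affymetrix-style detection probes (DNA).
# Agilent probes may carry a single optional 3' residue, written in parentheses.
name	mirna_sequence	agilent_probe	affymetrix_probe
mmu-miR-15a	UAGCAGCACAUAAUGGUUUGUG	CACAAACCATTATGTGCTGCT(A)	CACAAACCATTATGTGCTGCTA
mmu-miR-21	UAGCUUAUCAGACUGAUGUUGA	TCAACATCAGTCTGATAAG(C)	TCAACATCAGTCTGATAAGCTA
mmu-miR-34a	UGGCAGUGUCUUAGCUGGUUGU	ACAACCAGCTAAGACACTG(C)	ACAACCAGCTAAGACACTGCCA
mmu-miR-96	UUUGGCACUAGCACAUUUUUGCU	AGCAAAAATGTGCTAGTGCCA(A)	AGCAAAAATGTGCTAGTGCCAAA
mmu-miR-127	UCGGAUCCGUCUGAGCUUGGCU	AGCCAAGCTCAGACGGA(T)	AGCCAAGCTCAGACGGATCCGA
mmu-miR-146a	UGAGAACUGAAUUCCAUGGGUU	AACCCATGGAATTCAGTT(C)	AACCCATGGAATTCAGTTCTCA
mmu-miR-146b	UGAGAACUGAAUUCCAUAGGCU	AGCCTATGGAATTCAGTT(C)	AGCCTATGGAATTCAGTTCTCA
mmu-miR-182	UUUGGCAAUGGUAGAACUCACACCG	CGGTGTGAGTTCTAC(C)	CGGTGTGAGTTCTACCATTGCCAAA
mmu-miR-183	UAUGGCACUGGUAGAAUUCACU	AGTGAATTCTACCAGTGC(C)	AGTGAATTCTACCAGTGCCATA
mmu-miR-184	UGGACGGAGAACUGAUAAGGGU	ACCCTTATCAGTTCTCCGTCC(A)	ACCCTTATCAGTTCTCCGTCCA
mmu-miR-322	CAGCAGCAAUUCAUGUUUUGGA	TCCAAAACATGAATTGCTGCTG	TCCAAAACATGAATTGCTGCTG
mmu-miR-433	AUCAUGAUGGGCUCCUCGGUGU	ACACCGAGGAGCC(C)	ACACCGAGGAGCCCATCATGAT
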