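# Synthetic fixture catalog: recurrent genomic-disorder loci, clinically
# significant genes and susceptibility genes recurrently implicated in
# neurodevelopmental disorders. Coordinates are SYNTHETIC placeholders on a
# toy assembly, not genome-build positions; supply your own catalog TSV for
# real analyses. Gene entries are matched by symbol against the supplied
# gene annotation.
kind	name	chrom	start	end	symbol	required_type	min_reciprocal_overlap
recurrent_locus	22q11.2	chr22	18000000	21000000		any	0.5
recurrent_locus	15q11-q13	chr15	23000000	28500000		DUP	0.5
recurrent_locus	16p11.2_proximal	chr16	29500000	30200000		any	0.5
recurrent_locus	1q21.1_distal	chr1	146500000	147800000		any	0.5
recurrent_locus	16p12.1_distal	chr16	21900000	22500000		DUP	0.5
recurrent_locus	15q11.2_CYFIP1	chr15	22700000	23100000		any	0.5
significant_gene	NRXN1	chr2	50100000	51300000	NRXN1	any
significant_gene	ASTN2	chr9	119200000	120200000	ASTN2	any
significant_gene	CHD2	chr15	93400000	93600000	CHD2	DEL
significant_gene	CHAMP1	chr13	115000000	115100000	CHAMP1	DEL
susceptibility_gene	MACROD2	chr20	13900000	16100000	MACROD2	any
susceptibility_gene	DLGAP2	chr8	900000	1700000	DLGAP2	any
susceptibility_gene	DLG2	chr11	83100000	85300000	DLG2	any
susceptibility_gene	DPP6	chr7	153500000	154700000	DPP6	any
susceptibility_gene	GRIK2	chr6	101800000	102500000	GRIK2	any
susceptibility_gene	CNTN4	chr3	2100000	3100000	CNTN4	DUP
susceptibility_gene	CNTN6	chr3	1100000	1450000	CNTN6	DUP
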