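# Published gene-evidence rows for three soil-metagenome lasso peptide BGCs
# (40.1, 482.1, 44.1): BLAST-style description, gene size, domain annotation,
# and the curated lasso gene call used to validate the classifier.
# precursor_pass marks genes whose translated sequence passed manual
# precursor inspection (the published route for the 482.1 A genes).
bgc_id	gene_id	size_bp	description	domain_tag	precursor_pass	expected_label
40.1	8	975	Hypothetical protein [Acidobacteriia bacterium]	-	0	none
40.1	9	1905	Hypothetical protein [Acidobacteriia bacterium]	Asn_synthase	0	C
40.1	10	432	Hypothetical protein [Betaproteobacteria bacterium]	-	0	none
40.1	11	423	Lasso peptide biosynthesis B2 protein [Acidobacteriia bacterium]	PF13471	0	B2
40.1	12	294	PqqD family peptide modification chaperone [Acidobacteriia bacterium]	PF05402	0	B1
40.1	13	1116	Erythromycin biosynthesis sensory transduction protein eryC1 [Acidobacteria bacterium]	DegT_DnrJ_EryC1	0	none
482.1	10.1	276	Hypothetical protein DMG37_22385 [Acidobacteria bacterium]	PF05402	0	B1
482.1	10.2	276	PqqD family protein [Acidobacteriia bacterium]	-	0	B1
482.1	11	1404	Aminoglycoside phosphotransferase family protein [Acidobacteriia bacterium]	-	0	none
482.1	12	375	Lasso peptide biosynthesis B2 protein [Acidobacteria bacterium]	PF13471	0	B2
482.1	13	1929	Hypothetical protein [Acidobacteriia bacterium]	Asn_synthase	0	C
482.1	14	141	Hypothetical protein [Acidobacteria bacterium]	-	1	A
482.1	15	141	Hypothetical protein [Acidobacteria bacterium]	-	1	A
482.1	16	2118	Hypothetical protein DMG78_32005 [Acidobacteria bacterium]	-	0	none
44.1	8	822	ABC transporter permease [Acidobacteriia bacterium]	-	0	D
44.1	9	810	ABC transporter ATP-binding protein [Acidobacteriia bacterium]	ABC transporter ATP-binding protein	0	D
44.1	10	303	PqqD family peptide modification chaperone [Acidobacteriia bacterium]	PF05402	0	B1
44.1	11	471	Lasso peptide biosynthesis B2 protein [Acidobacteriia bacterium]	PF13471	0	B2
44.1	12	1863	Asparagine synthetase B [Acidobacteriia bacterium]	Asn_synthase	0	C
44.1	13	150	Hypothetical protein DMG36_15005 [Acidobacteria bacterium]	Predicted lasso peptide	0	A
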