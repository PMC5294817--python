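chrom	start	end	strand	ref	alleles	snp_id	lead_id	trait	score	sequence	position_in_motif
chr2	8442247	8442248	+	G	A/G	rs10174949	rs10174949	Self-reported allergy	4	AGATCATCGGGGTTT	11
chr15	50946814	50946815	+	A	A/G	rs11070802	rs2414059	QT interval	7	AGTGCACATGGTGCA	7
chr3	119278467	119278468	+	A	A/G	rs16829980	rs59374417	Vitiligo	6	AGTTCACTCAGTACT	5
chr19	49867015	49867016	+	C	C/G	rs2288480	rs2303759	Multiple sclerosis	4	GTGTCACCAAGGGCG	7
chr4	95088557	95088558	+	C	C/T	rs28613890	rs11097407	Bipolar disorder and schizophrenia	8	GTGGTCATTGAGTTC	14
chr6	109704441	109704442	+	T	C/T	rs3757230	rs1046943	Height	7	AGGTCATTGGGGAGG	3
chr6	109704450	109704451	+	A	A/C	rs3757231	rs1046943	Height	7	AGGTCATTGGGGAGG	12
chr5	95265555	95265556	+	G	A/G	rs4563648	rs7700895	IgG glycosylation	5	GGGTGAGAAAGTTTC	2
chr1	205641342	205641343	+	C	C/G	rs55915134	rs16856186	Pulmonary function decline	6	TGGGTGAGGGGGGGG	6
chr11	118575418	118575419	-	G	C/T	rs625735	rs494459	Height	9.18	GTGTCAAAGGGTTCA	10
chr11	128206409	128206410	+	C	C/T	rs6590322	rs6590322	Hippocampal atrophy	8	AAAGTCAGAGAGGAC	7
chr15	49167995	49167996	+	G	A/G	rs73402209	rs8023445	Major depressive disorder	9.18	AGGTCAAAGAGGTCG	14
chr21	35348499	35348500	-	C	A/G	rs743418	rs2032314	Red blood cell traits	4	AGGCTGCTGGGTCCA	12
chr5	150169882	150169883	+	A	A/T	rs74973123	rs13361189	Crohn's disease	5	ATGTTAAAGGGTTTA	7
chr9	123664122	123664123	+	A	A/G	rs7859805	rs881375	Rheumatoid arthritis	6	GGGGCAAAAGGTGTG	5
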