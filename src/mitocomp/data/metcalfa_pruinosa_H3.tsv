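#genome_length=16314
#record_id=MN417319
#organism=Metcalfa pruinosa (H3)
name	ftype	strand	start	end	anticodon	start_codon	stop_codon
trnI	tRNA	+	1	65	GAT
trnQ	tRNA	-	69	137	TTG
trnM	tRNA	+	137	202	CAT
ND2	PCG	+	203	1180		ATT	TAA
trnW	tRNA	+	1179	1246	TCA
trnC	tRNA	-	1239	1302	GCA
trnY	tRNA	-	1310	1373	GTA
COI	PCG	+	1374	2918		ATC	TAA
trnL2	tRNA	+	2921	2983	TAA
COII	PCG	+	2984	3661		ATA	TAA
trnK	tRNA	+	3672	3741	CTT
trnD	tRNA	+	3742	3810	GTC
ATP8	PCG	+	3811	3966		ATT	TAA
ATP6	PCG	+	3960	4611		ATG	T
COIII	PCG	+	4612	5394		ATG	TAA
trnG	tRNA	+	5401	5465	TCC
ND3	PCG	+	5467	5817		ATG	TAA
trnA	tRNA	+	5816	5883	TGC
trnR	tRNA	+	5901	5964	TCG
trnN	tRNA	+	5990	6054	GTT
trnS1	tRNA	+	6056	6116	GCT
trnE	tRNA	+	6120	6184	TTC
trnF	tRNA	-	6197	6261	GAA
ND5	PCG	-	6268	7950		ATG	TAA
trnH	tRNA	-	7952	8016	GTG
ND4	PCG	-	8031	9362		ATG	TAG
ND4L	PCG	-	9362	9634		ATG	TAA
trnT	tRNA	+	9637	9700	TGT
trnP	tRNA	-	9708	9773	TGG
ND6	PCG	+	9775	10275		ATA	TAA
CytB	PCG	+	10280	11404		ATG	TAA
trnS2	tRNA	+	11420	11482	TGA
ND1	PCG	-	11492	12442		ATG	TAA
trnL1	tRNA	-	12444	12508	TAG
lrRNA	rRNA	-	12509	13734
trnV	tRNA	-	13735	13807	TAC
srRNA	rRNA	-	13808	14524
AT_rich	control	+	14525	16314
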