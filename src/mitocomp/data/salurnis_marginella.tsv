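#genome_length=16126
#record_id=MT628542
#organism=Salurnis marginella
name	ftype	strand	start	end	anticodon	start_codon	stop_codon
trnI	tRNA	+	1	62	GAT
trnQ	tRNA	-	81	149	TTG
trnM	tRNA	+	149	214	CAT
ND2	PCG	+	215	1180		ATT	TAA
trnW	tRNA	+	1179	1243	TCA
trnC	tRNA	-	1236	1295	GCA
trnY	tRNA	-	1296	1356	GTA
COI	PCG	+	1362	2897		ATG	TAA
trnL2	tRNA	+	2898	2959	TAA
COII	PCG	+	2960	3640		ATA	TAA
trnK	tRNA	+	3641	3709	CTT
trnD	tRNA	+	3710	3772	GTC
ATP8	PCG	+	3773	3925		ATT	TAA
ATP6	PCG	+	3919	4570		ATG	T
COIII	PCG	+	4571	5353		ATG	TAA
trnG	tRNA	+	5355	5415	TCC
ND3	PCG	+	5451	5786		ATT	TAA
trnA	tRNA	+	5786	5848	TGC
trnR	tRNA	+	5849	5909	TCG
trnN	tRNA	+	5911	5973	GTT
trnS1	tRNA	+	5972	6031	GCT
trnE	tRNA	+	6034	6095	TTC
trnF	tRNA	-	6094	6156	GAA
ND5	PCG	-	6156	7835		GTG	TAA
trnH	tRNA	-	7836	7897	GTG
ND4	PCG	-	7898	9221		ATG	T
ND4L	PCG	-	9223	9495		ATG	TAA
trnT	tRNA	+	9498	9558	TGT
trnP	tRNA	-	9560	9622	TGG
ND6	PCG	+	9624	10121		ATA	TAA
CytB	PCG	+	10114	11235		ATG	TAA
trnS2	tRNA	+	11235	11295	TGA
ND1	PCG	-	11289	12230		ATG	TAA
trnL1	tRNA	-	12232	12293	TAG
lrRNA	rRNA	-	12294	13497
trnV	tRNA	-	13498	13567	TAC
srRNA	rRNA	-	13567	14290
AT_rich	control	+	14291	16126
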