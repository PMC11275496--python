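# Published annotation of the Myophonus caeruleus mitogenome (GenBank MN564936, 16815 bp, circular).
# Start/stop codons where annotated: nad1 ATG/TA-, nad2 ATG/TAA, cox1 GTG/AGG, cox2 ATG/TAA,
# atp8 ATG/TAA, atp6 ATG/TAA, cox3 ATG/T--, nad3 ATG/TAA, nad4l ATG/TAA, nad4 ATG/T--,
# nad5 ATG/AGA, cob ATG/TAA, nad6 ATG/TAG.
name	class	strand	start	end	anticodon
trnF	tRNA	H	1	68	GAA
rrnS	rRNA	H	68	1047
trnV	tRNA	H	1047	1116	TAC
rrnL	rRNA	H	1133	2711
trnL2	tRNA	H	2714	2788	TAA
nad1	PCG	H	2794	3764
trnI	tRNA	H	3779	3850	GAT
trnQ	tRNA	L	3855	3925	TTG
trnM	tRNA	H	3925	3993	CAT
nad2	PCG	H	3994	5034
trnW	tRNA	H	5034	5104	TCA
trnA	tRNA	L	5106	5174	TGC
trnN	tRNA	L	5179	5251	GTT
trnC	tRNA	L	5252	5318	GCA
trnY	tRNA	L	5318	5388	GTA
cox1	PCG	H	5390	6940
trnS2	tRNA	L	6932	7006	TGA
trnD	tRNA	H	7010	7078	GTC
cox2	PCG	H	7087	7770
trnK	tRNA	H	7772	7839	TTT
atp8	PCG	H	7841	8008
atp6	PCG	H	7999	8682
cox3	PCG	H	8688	9471
trnG	tRNA	H	9472	9540	TCC
nad3	PCG	H	9541	9891
trnR	tRNA	H	9893	9962	TCG
nad4l	PCG	H	9964	10260
nad4	PCG	H	10254	11631
trnH	tRNA	H	11632	11702	GTG
trnS1	tRNA	H	11703	11768	GCT
trnL1	tRNA	H	11768	11838	TAG
nad5	PCG	H	11839	13656
cob	PCG	H	13665	14807
trnT	tRNA	H	14811	14879	TGT
trnP	tRNA	L	14886	14955	TGG
nad6	PCG	L	14973	15491
trnE	tRNA	L	15493	15564	TTC
d-loop	control_region	H	15569	16518
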