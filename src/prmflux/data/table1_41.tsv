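accession	gene	category
Q9C0C7	AMBRA1	Mitophagy receptor
O94817	ATG12	Lipidation machinery
O75143	ATG13	Initiation
Q2TAZ0	ATG2A	Lipidation machinery
Q9NT62	ATG3	Lipidation machinery
Q8WYN0	ATG4A	Lipidation machinery
Q9Y4P1	ATG4B	Lipidation machinery
Q9H1Y0	ATG5	Lipidation machinery
O95352	ATG7	Lipidation machinery
Q7Z3C6	ATG9A	Autophagosome biogenesis
Q12981	BNIP1	Autophagosome biogenesis
Q12983	BNIP3	Mitophagy receptor
O60238	BNIP3L	Mitophagy receptor, pexophagy receptor
Q13137	CALCOCO2	Ubiquitylated substrate receptor
Q9ULG6	CCPG1	Reticulophagy receptor
Q14318	FKBP8	Mitophagy receptor
Q9GJW7	GABARAP	Mammalian Atg8 protein
Q9H0R8	GABARAPL1	Mammalian Atg8 protein
P60520	GABARAPL2	Mammalian Atg8 protein
Q9H492	MAP1LC3A	Mammalian Atg8 protein
Q9BXW4	MAP1LC3C	Mammalian Atg8 protein
Q14596	NBR1	Ubiquitinated substrate receptor, pexophagy receptor
Q13772	NCOA4	Ferritinophagy receptor
Q9UHK0	NUFIP1	Proposed ribophagy receptor
Q96CV9	OPTN	Ubiquitinated substrate receptor
Q99623	PHB2	Mitophagy receptor
Q96AD5	PNPLA2	Lipophagy receptor
Q8TDY2	RB1CC1	Autophagy initiation
Q9H6L5	RETREG1	Reticulophagy receptor
P23443	RPS6KB1	Signaling
O95197	RTN3	Reticulophagy receptor
Q13501	SQSTM1	Ubiquitylated substrate receptor
O95210	STBD1	Glycophagy receptor
Q86VP1	TAX1BP1	Ubiquitinated substrate receptor
P19484	TFEB	Lysosomal biogenesis
Q15025	TNIP1	Autophagy receptor
Q9H0E2	TOLLIP	Ubiquitinated substrate receptor
O75385	ULK1	Signaling, initiation
Q969T9	WBP2	Autophagosome biogenesis
Q8IZQ1	WDFY3	Ubiquitylated substrate receptor
Q9Y4P8	WIPI2	Autophagosome biogenesis
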