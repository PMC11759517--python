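accession	gene	category
P23443	RPS6KB1	Autophagy regulation
P19484	TFEB	Autophagy regulation
O75385	ULK1	Initiation complex
Q8TDY2	RB1CC1	Initiation complex
O75143	ATG13	Initiation complex
Q2TAZ0	ATG2A	Autophagosome biogenesis
Q7Z3C6	ATG9A	Autophagosome biogenesis
Q9Y4P8	WIPI2	Autophagosome biogenesis
Q12981	BNIP1	Autophagosome biogenesis
Q969T9	WBP2	Autophagosome biogenesis
Q9NT62	ATG3	Lipidation machinery
O95352	ATG7	Lipidation machinery
O94817	ATG12	Lipidation machinery
Q9H1Y0	ATG5	Lipidation machinery
Q8WYN0	ATG4A	Lipidation machinery
Q9H0R8	GABARAPL1	Atg8-family protein
P60520	GABARAPL2	Atg8-family protein
Q13501	SQSTM1	Selective autophagy receptor
Q14596	NBR1	Selective autophagy receptor
Q96CV9	OPTN	Selective autophagy receptor
Q13137	CALCOCO2	Selective autophagy receptor
Q86VP1	TAX1BP1	Selective autophagy receptor
Q8IZQ1	WDFY3	Selective autophagy receptor
Q9ULG6	CCPG1	Selective autophagy receptor
Q9H6L5	RETREG1	Selective autophagy receptor
O95197	RTN3	Selective autophagy receptor
O60238	BNIP3L	Selective autophagy receptor
Q9H0E2	TOLLIP	Selective autophagy receptor
Q14318	FKBP8	Selective autophagy receptor
Q12983	BNIP3	Selective autophagy receptor
Q9C0C7	AMBRA1	Selective autophagy receptor
Q99623	PHB2	Selective autophagy receptor
Q13772	NCOA4	Selective autophagy receptor
O95210	STBD1	Selective autophagy receptor
Q96AD5	PNPLA2	Selective autophagy receptor
Q9UHK0	NUFIP1	Selective autophagy receptor
Q15025	TNIP1	Selective autophagy receptor
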