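No.	Age	Sex	Subtypes	Status	Conditioning Regimen	Complication during ASCR	Progression	PFS
598	36	M	GCB	Salvage	CBV	Pneumonia	No	35.5
592	51	M	non-GCB	Salvage	BEAC	-	Yes	9.3
602	29	M	non-GCB	Salvage	CBV	-	No	34.0
535	23	F	GCB	Consolidation	CBV	-	Yes	4.9
457	45	M	non-GCB	Salvage	CBV	-	Yes	12.6
473	50	F	non-GCB	Salvage	CBV	-	Yes	7.1
512	45	M	non-GCB	Salvage	CBV	-	No	46.6
519	44	M	GCB	Consolidation	CBV	-	No	42.5
383	40	F	non-GCB	Consolidation	R-CBV	-	Yes	23.5
419	62	M	non-GCB	Salvage	BEAM	Pneumonia & AF	Yes	18.8
486	49	M	non-GCB	Salvage	CBV	Diarrhea	Yes	6.7
615	55	F	non-GCB	Salvage	CBV	-	Yes	6.0
548	65	M	non-GCB	Salvage	CBV	-	No	32.5
559	32	M	non-GCB	Salvage	CBV	-	No	38.3
601	20	M	GCB	Salvage	CBV	-	No	30.2
617	52	F	non-GCB	Salvage	CBV	-	No	21.8
620	47	M	non-GCB	Salvage	CBV	-	No	17.5
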