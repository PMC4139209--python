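# Transcribed enrichment table: biological processes over-represented in the 132-gene
# shared-target list (p-values as printed by the original web-tool analysis; carried as
# a fixture for output-shape comparisons, not as a reproduction target).
term_name	p_value	genes
Transcription regulation	0.0053	AFF4,CITED2,EHF,ESRRG,FOXO1,GABPA,GLIS2,MBD2,MDFIC,NCL,NFIB,PBX1,RBPMS,SOX6,SUZ12,TRP63,YY1,ZFP238,ZFP654,ZFP93,ZBTB33
Zinc finger	0.0098	ESRRG,GLIS2,MBNL1,PCLO,PJA2,SUZ12,UBC,USP33,YY1,ZCCHC8,ZFP238,ZFP36L1,ZFP654,ZFP704,ZFP93,ZRSR2,ZBTB33
Skeletal muscle tissue development	0.0182	CAV1,CAV2,HOMER1,MBNL1
Protein kinase cascade	0.0361	SRPK2,CAV1,MDFIC,RPS6KB1,NRK,SOCS5
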