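gene_symbol	protein_name	accession	peptide_sequence	site	3KTR/3KT	A549/3KT	H322/3KT	H1299/3KT
BAT3	Large proline-rich protein BAT3	P46379	APPQTHLPSGASSGTGSASATHGGGpSPPGTR	S113	1.718	1.680	2.423	0.806
BAT3	Large proline-rich protein BAT3	P46379	APPQTHLPSGASSGTGpSASATHGGGSPPGTR	S104	1.717	1.664	2.400	0.776
BAT3	Large proline-rich protein BAT3	P46379	APPQTHLPSGASSGTGSASApTHGGGSPPGTR	T108	1.715	1.679	2.420	0.803
BCLAF1	Bcl-2-associated transcription factor 1	Q9NYF8	SSATSGDIWPGLSAYDNpSPR	S222	1.104	1.612	1.176	0.688
BCLAF1	Bcl-2-associated transcription factor 1	Q9NYF8	SSATSGDIWPGLpSAYDNSPR	S217	1.098	1.612	1.176	0.688
COBRA1	Negative elongation factor B	Q8WX92	KPSPAQAAEpTPALELPLPSVPAPAPL	T564	1.593	1.540	1.829	0.514
COBRA1	Negative elongation factor B	Q8WX92	KPpSPAQAAETPALELPLPSVPAPAPL	S557	1.589	1.531	1.827	0.477
CTTN	Cortactin	Q8N707	TQpTPPVSPAPQPTEER	T364	1.065	1.052	1.236	-1.680
FAM129B	Niban-like protein	Q96TA1	AAPEASpSPPASPLQHLLPGK	S679	2.107	1.752	1.556	-9999
LMNA	Lamin-A/C	P02545	LSPpSPTSQR	S392	1.737	1.102	1.475	0.977
LMNA	Lamin-A/C	P02545	LpSPSPTSQR	S390	1.193	1.098	1.084	0.975
MAPK1	MAP Kinase, ERK2	P28482	VADPDHDHTGFLTEpYVATR	Y187	1.946	1.024	1.599	-1.308
MICAL1	Calponin and LIM domain containing 1	Q8TDZ2	LSpSPERQR	S829	1.737	1.108	1.220	0.972
PPP1R13L	RelA-associated inhibitor	Q8WUF5	SESAPTLHPYSPLpSPK	S113	1.218	1.235	1.688	0.532
SRRM2	Serine/arginine repetitive matrix protein 2	Q9UQ35	SRpTPPSAPSQSR	T2409	1.361	1.838	1.460	0.623
ABI1	Abl interactor 1	Q8IZP0	LGSQHpSPGR	S225	-1.184	-1.181	-1.932	-0.669
API5	Apoptosis inhibitor 5	Q9BZZ5	RASEDTTSGpSPPKK	S464	-1.704	-3.756	-3.442	0.429
PALLD	Palladin	Q8WX93	pSPSGHPHVR	S880	-1.017	-1.676	-1.510	-0.586
TMEM40	Transmembrane protein 40	Q8WWA1	RGpSDPASGEVEASQLR	S153	-1.293	-5.644	-2.08	-9999
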