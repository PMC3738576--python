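group	gene	intron_location	intron_length_nt	cdna_clone
A	ath|BTL1/RHC1a	5'UTR	741	R24044
A	ath|BTL2	5'UTR	792	R10352
A	ath|BTL3	5'UTR	675	R24260
A	osa|LOC_Os03g22830	5'UTR	821	J023049J20
A	osa|LOC_Os05g41520	intronless	-	OSIGCSN035B04
A	osa|LOC_Os01g58780	5'UTR	562	J033125G22
B	ath|BTL4	5'UTR	463	R11278
B	ath|BTL5	5'UTR	337	R25506
B	ath|BTL6	5'UTR	453	R14449
B	ath|BTL7	5'UTR	299	BX837858
B	osa|LOC_Os05g40980	5'UTR	764, 31	J013096K09
B	osa|LOC_Os03g59760	5'UTR; 3'UTR	551; 109	J013111A16
B	osa|LOC_Os03g20870	5'UTR	322	J013135G08
B	osa|LOC_Os01g16950	5'UTR	420	J023108I11
C	ath|BTL9/AtRDUF2	intronless	-	R13790
C	ath|BTL10/AtRDUF1	intronless	-	R24103
C	ath|BTL11	intronless	-	R21507
C	osa|LOC_Os03g16480	intronless	-	J023018C07
C	osa|LOC_Os05g01940	intronless	-	J013094N21
C	osa|LOC_Os01g74040	intronless	-	J065019N08
D	ath|BTL12	intronless	-	R16110
D	ath|BTL13	intronless	-	BX822831
D	ath|BTL14	intronless	-	NA
D	ath|BTL16	5'UTR	126	BX832364
D	osa|LOC_Os11g02670	5'UTR; 3'UTR	113; 920, 95	J033119L05
D	osa|LOC_Os12g02620	5'UTR	113	J033073H23
D	osa|LOC_Os08g36170	3'UTR	4332	R21874
E	ath|BTL15	intronless	-	NA
E	ath|BTL17	intronless	-	NA
E	osa|LOC_Os06g10800	intronless	-	NA
E	osa|LOC_Os02g52870	3'UTR	93	OSIGCSA056L07
F	ath|BTL8	3'UTR	1143	R21874
F	osa|LOC_Os10g34590	3'UTR	2123	J033094G14
F	osa|LOC_Os06g01200	5'UTR	2855	J033105E24
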