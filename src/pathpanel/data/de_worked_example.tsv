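# Worked-example differential-expression table: 57 genes called between
# metaplastic (MpBC) and invasive ductal triple-negative (TNBC) breast cancer
# samples on a 336-query-gene counts panel. Columns: gene symbol, log2 fold
# change (MpBC vs TNBC), raw likelihood-ratio p, and the published
# FDR-adjusted q (BH step-up over the 336 panel genes).
gene	log2fc	p	q
PTHLH	4.11	1.90E-05	4.43E-04
IGFBP3	1.97	6.59E-05	1.23E-03
ICAM1	1.71	6.57E-04	8.83E-03
IER3	1.72	8.62E-04	1.07E-02
BST2	1.56	1.23E-03	1.43E-02
HAS2	1.93	2.48E-03	2.45E-02
PDPN	1.95	2.47E-03	2.45E-02
IL6	2.31	2.64E-03	2.54E-02
COL5A1	1.52	3.86E-03	3.12E-02
FN1	1.53	3.59E-03	3.12E-02
IL8	2.02	4.87E-03	3.80E-02
PLAT	1.77	5.52E-03	3.99E-02
COL5A2	1.52	5.77E-03	4.04E-02
COL1A1	1.67	5.93E-03	4.07E-02
INHBA	1.49	6.65E-03	4.47E-02
CDH11	1.15	7.22E-03	4.53E-02
MYLK	1.32	7.13E-03	4.53E-02
CTGF	1.37	7.31E-03	4.53E-02
PRR9	-5.10	2.55E-15	8.58E-13
LCE3E	-31.84	3.33E-14	5.60E-12
LCE1F	-5.76	1.43E-11	1.60E-09
FAM25A	-3.87	2.89E-10	2.43E-08
AGPAT9	-2.65	5.29E-10	3.45E-08
DUSP8	-2.14	6.17E-10	3.45E-08
FAM83A-AS1	-3.61	4.15E-08	1.99E-06
FGFBP2	-0.26	1.20E-07	5.06E-06
CHAC1	-2.84	3.57E-07	1.33E-05
HSPE1	-2.07	1.10E-06	3.69E-05
CD24	-2.90	1.57E-06	4.80E-05
ALOXE3	-3.54	4.81E-06	1.35E-04
ERBB2	-1.24	1.22E-05	3.16E-04
RIMS3	-1.36	1.98E-05	4.43E-04
ACTBL2	-3.04	2.11E-05	4.44E-04
KLK6	-3.51	3.69E-05	7.30E-04
LCE3D	-4.12	8.55E-05	1.51E-03
ABCB1	-2.20	1.15E-04	1.94E-03
LOC100130238	-2.86	2.12E-04	3.39E-03
BMP6	-2.06	4.06E-04	6.19E-03
TMCC2	-1.55	5.38E-04	7.86E-03
LEP	-2.77	6.05E-04	8.47E-03
ZSCAN12P1	-1.70	8.46E-04	1.07E-02
CCL26	-1.96	9.29E-04	1.11E-02
MAL	-2.26	1.38E-03	1.54E-02
ERBB3	-1.85	2.29E-03	2.41E-02
NOV	-1.52	2.26E-03	2.41E-02
PAPL	-1.91	2.88E-03	2.69E-02
DSCAM	-2.87	3.76E-03	3.12E-02
KRT81	-2.34	3.69E-03	3.12E-02
TAGLN3	-2.02	3.90E-03	3.12E-02
ZNF165	-1.39	3.44E-03	3.12E-02
CALML5	-2.55	5.00E-03	3.82E-02
DIRAS3	-1.69	5.52E-03	3.99E-02
ARHGAP33	-0.66	5.58E-03	3.99E-02
RASD2	-1.24	6.92E-03	4.53E-02
FAM46B	-1.20	7.41E-03	4.53E-02
PDGFB	-0.79	8.17E-03	4.90E-02
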