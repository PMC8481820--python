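gene_id	pval_oa	pval_md	pval_meta
DCDC1	2.35e-08	5.00e-05	3.13e-11
AMIGO3	2.18e-09	1.06e-05	9.91e-11
AMT	4.91e-07	4.40e-06	2.04e-09
BSN	3.13e-08	2.52e-07	2.73e-11
CDHR4	1.35e-08	2.95e-07	3.20e-11
FAM212A	1.12e-08	4.41e-07	2.91e-11
GMPPB	2.18e-09	1.06e-05	9.91e-11
GPX1	3.42e-07	6.22e-06	1.18e-09
IP6K1	1.21e-09	2.08e-06	2.01e-11
KLHDC8B	9.42e-05	1.21e-07	1.03e-09
MST1	4.08e-08	5.68e-05	1.62e-09
RNF123	1.14e-09	4.82e-06	3.25e-11
TRAIP	3.35e-10	1.40e-05	3.87e-11
UBA7	2.44e-09	2.57e-07	8.45e-12
PHF2	2.57e-05	4.04e-06	2.36e-09
ANKK1	2.02e-05	6.35e-09	3.83e-11
DRD2	1.16e-06	3.03e-14	1.78e-15
CDH13	2.37e-05	2.94e-08	1.19e-10
STRA6	2.96e-07	5.35e-05	1.20e-09
FOXP2	1.14e-07	1.96e-06	1.07e-11
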