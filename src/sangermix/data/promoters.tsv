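promoter	lambda	beta
pSal	1.05	0.07
pTet	0.52	0.14
pBet	0.46	0.05
pBAD	0.98	0.06
pLux	0.84	0.19
pVan	0.64	0.01
pTtg	0.11	0.13
pTac	0.56	0.02
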