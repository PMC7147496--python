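accession	mirna_id	mature_seq	precursor_length	gc_percent	mfe	amfe	mfei
HO190899.1	zma-miR528a-5p	TGGAAGGGGCATGCAGAGGAG	79	51.3	35.5	46.71	0.91
HO190899.1	zma-miR528b-5p	TGGAAGGGGCATGCAGAGGAG	79	51.3	35.5	46.71	0.91
HO191179.1	>cca-miR390	AAGCTCAGGAGGGATAGCG	107	43	42.55	39.76	0.92
HO191179.1	>lus-miR390a	AAGCTCAGGAGGGATAGCGCC	106	43.4	42.95	40.51	0.93
HO191179.1	>lus-miR390b	AAGCTCAGGAGGGATAGCGCC	106	43.4	42.95	40.51	0.93
HO191179.1	>csi-miR390b-5p	AGCTCAGGAGGGATAGCGCC	105	43.81	41.65	39.66	0.9
HO191179.1	>lus-miR390c	AAGCTCAGGAGGGATAGCGCC	106	43.4	42.95	40.51	0.93
HO191179.1	>ppt-miR390c-5p	AGCTCAGGAGGGATAGCGCC	105	43.81	41.65	39.66	0.9
HO191179.1	>lus-miR390d	AAGCTCAGGAGGGATAGCGCC	106	43.4	42.95	40.51	0.93
HO191179.1	>gma-miR390e	AGCTCAGGAGGGATAGCGCC	105	43.81	41.65	39.66	0.9
HO191179.1	>gma-miR390f	AAGCTCAGGAGGGATAGCGCC	106	43.4	42.95	40.51	0.93
HO191179.1	>gma-miR390g	AAGCTCAGGAGGGATAGCGCC	106	43.4	42.95	40.51	0.93
HO191179.1	>atr-miR390.1	TAAAGCTCAGGAGGGATAGCG	111	41.44	45.25	40.76	0.98
HO194934.1	>ath-miR414	GACGATGATGATGAAGATGA	169	47.93	47.8	28.28	0.59
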