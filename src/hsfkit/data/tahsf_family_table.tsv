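Gene	Full or partial (C or N) ORF	No. of amino acids	pI	Mol. wt (kDa)	Affymetrix probe set ID (no. of probe matches)
TaHsfA1a	Full	529	4.99	58.1
TaHsfA1b	Full	522	4.91	57.5	Ta.8059.1.S1_at (7)
TaHsfA1c	Almost full	NA	NA	NA
TaHsfA2a	Full	353	5.36	39.7	TaAffx.92707.2.S1_at (11)
TaHsfA2b	Full	413	4.99	45.6	Ta.6737.2.S1_a_at (11), TaAffx.105519.1.S1_at (8)
TaHsfA2c	Full	404	5.06	44.8	TaAffx.105519.1.S1_at (8)
TaHsfA2d	Partial (C)	NA	NA	NA	TaAffx.92707.1.S1_at (9)
TaHsfA2e	Partial (C)	NA	NA	NA	Ta.6737.2.S1_a_at (11)
TaHsfA2f	Partial (C)	NA	NA	NA	Ta.1276.1.A1_at (10)
TaHsfA2g	Partial (N)	NA	NA	NA
TaHsfA2h	Full	405	5.06	44.9	TaAffx.105519.1.S1_at (8)
TaHsfA2i	Partial (N)	NA	NA	NA
TaHsfA3a	Full	499	5.7	54.8	TaAffx.12296.1.S1_at (11)
TaHsfA3b	Partial (C)	NA	NA	NA
TaHsfA4a	Full	432	5.36	48.4
TaHsfA4b	Full	441	5.18	49.5
TaHsfA4c	Full	448	4.91	50.2	TaAffx.120360.1.A1_at (4)
TaHsfA4d	Full	442	5.11	49.7	TaAffx.5995.1.S1_at (8), TaAffx.120360.1.A1_at (5)
TaHsfA4e	Full	445	4.93	49.9	TaAffx.120360.1.A1_at (11)
TaHsfA4f	Partial (C)	NA	NA	NA
TaHsfA5a	Full	458	5.21	49.9
TaHsfA5b	Full	455	5.33	49.9
TaHsfA6a	Full	341	5.02	39.5	Ta.27873.1.A1_at (9)
TaHsfA6b	Partial (C)	NA	NA	NA
TaHsfA6c	Partial (C)	NA	NA	NA	Ta.28772.1.S1_at (6)
TaHsfA6d	Partial (C)	NA	NA	NA	Ta.28772.1.S1_at (9)
TaHsfA6e	Full	370	5.03	42	Ta.28772.1.S1_at (6)
TaHsfA6f	Partial (N)	NA	NA	NA
TaHsfA7a	Full	353	4.79	38.2
TaHsfA7b	Full	351	4.83	38.2
TaHsfA8a	Full	384	5.15	43.1	TaAffx.40092.1.S1_at (7)
TaHsfA8b	Partial (C)	NA	NA	NA	TaAffx.40092.1.S1_at (5)
TaHsfA8c	Partial (C)	NA	NA	NA	TaAffx.40092.1.S1_at (11)
TaHsfB1a	Full	298	9.5	32.2	Ta.11671.1.S1_at (9)
TaHsfB1b	Full	298	9.31	32.3
TaHsfB1c	Full	298	9.2	32.1	Ta.11671.2.S1_x_at (6)
TaHsfB2a	Full	314	9.46	34.7
TaHsfB2b	Full	374	5.44	40.4
TaHsfB2c	Full	397	4.89	41.4
TaHsfB2d	Full	396	4.89	41.1
TaHsfB2e	Full	397	5.28	41.3	Ta.18067.2.S1_x_at (4)
TaHsfB4a	Full	320	6.55	35.3
TaHsfB4b	Partial (N)	NA	NA	NA
TaHsfB4c	Partial (N)	NA	NA	NA
TaHsfC1a	Full	325	6.08	35.8
TaHsfC1b	Full	236	6.91	26.1	Ta.8266.1.A1_s_at (11), TaAffx.34778.1.S1_at (11)
TaHsfC1c	Full	234	7.65	25.8	Ta.8266.1.A1_s_at (7)
TaHsfC1d	Full	241	8.76	26.4	Ta.8266.1.A1_s_at (11)
TaHsfC1e	Full	325	5.94	35.7
TaHsfC2a	Full	263	6.11	28.0	Ta.5852.1.A1_at (9), Ta.5852.1.A1_x_at (9)
TaHsfC2b	Full	270	6.92	28.7
TaHsfC2c	Almost full	NA	NA	NA
TaHsfC2d	Full	274	6.98	30	Ta.13964.1.S1_at (11)
TaHsfC2e	Full	276	6.46	30.3
TaHsfC2f	Full	264	5.43	29.1	Ta.13964.1.S1_at (11)
TaHsfC2g	Full	275	8.4	30.2	Ta.25627.1.A1_at (11), Ta.25627.1.A1_x_at (11)
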