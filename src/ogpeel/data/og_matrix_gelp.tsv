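Orthogroup	AMBTC	PHODA	MUSAC	ORYSA	VITVI	PRUMU	THECC	ARATH	COFCA	exon_structure
OG-GELP-C1a	1	4	3	3	1	1	1	1	1	(1), (2)
OG-GELP-C1b	1	2	2	4	5	3	4	8	2	(1), (2)
OG-GELP-C2a	1	3	1	1	2	2	2	2	2	(1), (2), (3), (4), (5), (6)
OG-GELP-C2b	1	1	1	1	1	1	1	1	1	(1), (2), (3), (4), (5), (6)
OG-GELP-C2c	1	1	2	2	1	1	1	1	2	(1), (2+3), (4), (5), (6)
OG-GELP-C3	1	2	3	2	6	8	1	5	2	(1), (2), (3), (4), (5)
OG-GELP-C4a	1	1	2	1	2	4	3	3	1	(1), (2), (3), (4), (5)
OG-GELP-C4b	1	2	4	6	4	3	3	3	1	(1), (2), (3), (4), (5)
OG-GELP-C4c	1	1	1	1	1	1	1	1	1	(1), (2), (3), (4), (5)
OG-GELP-C4d	1	1	1	1	2	1	1	1	1	(1+2+3), (4+5)
OG-GELP-C4e	1	2	4	2	6	5	3	2	1	(1), (2), (3), (4), (5)
OG-GELP-C4f	4	-	-	-	4	4	7	2	3	(1), (2), (3), (4), (5)
OG-GELP-C4g	8	2	1	4	1	1	4	1	10	(1), (2), (3), (4), (5)
OG-GELP-C4h	-	9	12	16	1	3	2	11	7	(1), (2), (3), (4), (5)
OG-GELP-C4i	-	8	10	23	1	1	1	1	1	(1), (2), (3), (4), (5)
OG-GELP-C5a	2	2	-	-	1	1	1	-	1	(1), (2'), (3'), (4), (5)
OG-GELP-C5b	8	-	-	-	7	11	9	11	6	(1), (2'), (3'), (4), (5)
OG-GELP-C6a	2	1	1	1	1	2	4	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C6b	1	1	2	1	1	1	1	2	1	(1), (2'), (3'), (4), (5)
OG-GELP-C6c	1	1	1	1	1	2	1	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C7a	1	1	1	1	1	1	1	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C7b	1	2	2	3	8	7	4	8	3	(1), (2'), (3'), (4), (5)
OG-GELP-C7c	1	1	1	2	1	1	1	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C7d	1	1	2	-	2	1	2	2	1	(1), (2'), (3'), (4), (5)
OG-GELP-C7e	1	-	1	-	1	-	-	1	-	(1), (2'), (3'), (4), (5)
OG-GELP-C7f	1	-	-	-	7	1	6	2	1	(1), (2'), (3'), (4), (5)
OG-GELP-C7g	1	1	1	1	1	3	1	-	1	(1+2'), (3'), (4), (5)
OG-GELP-C7h	1	-	-	-	1	-	-	-	-	(1), (2'), (3'), (4), (5)
OG-GELP-C8a	2	1	-	1	1	1	1	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C8b	1	6	5	7	3	5	4	3	2	(1+2'), (3'+4), (5)
OG-GELP-C8c	1	-	-	-	1	-	1	1	2	(1), (2'), (3'), (4), (5)
OG-GELP-C8d	1	1	1	2	-	1	-	1	-	(1+2'+3'), (4), (5)
OG-GELP-C8e	-	-	1	1	2	1	3	7	2	(1+2'+3'), (4), (5)
OG-GELP-C8f	1	5	5	7	7	5	2	21	2	(1), (2'), (3'), (4), (5)
OG-GELP-C9a	1	1	2	2	2	1	1	1	2	(1), (2'), (3'), (4), (5)
OG-GELP-C9b	1	2	2	1	2	2	2	4	3	(1), (2'), (3'), (4), (5)
OG-GELP-C10a	1	1	-	2	1	1	1	-	-	(1), (2'+3'), (4), (5)
OG-GELP-C10b	2	1	1	1	1	3	1	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C10c	1	-	-	-	1	1	1	1	1	(1), (2'), (3'+4), (5)
OG-GELP-C10d	3	1	1	1	1	1	1	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C10e	1	1	1	2	1	1	1	1	1	(1), (2'), (3'a), (3'b), (4), (5)
OG-GELP-C10f	1	1	2	3	1	2	1	1	1	(1), (2'), (3'), (4), (5)
OG-GELP-C10g	1	4	5	5	4	3	3	4	4	(1), (2'), (3'), (4), (5)
OG-GELP-C10h	3	6	10	10	2	3	2	-	1	(1), (2'), (3'), (4), (5)
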