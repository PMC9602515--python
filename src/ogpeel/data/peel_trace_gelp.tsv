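step	n_total	n_per_species	positions	cluster	cluster_size	cluster_per_species	support	terminal
1	248	66-81-101	102	Cluster 1	14	2-6-6	0.99	0
2	234	64-75-95	113	Cluster 2	12	3-5-4	1.00	0
3	222	61-70-91	135	Cluster 3	9	1-2-6	1.00	0
4	213	60-68-85	126	Cluster 4	65	17-26-22	0.96	0
5	148	43-42-63	179	Cluster 5	20	10-2-8	1.00	0
6	128	33-40-55	195	Cluster 6	10	4-3-3	0.98	0
7	118	29-37-52	204	Cluster 7	36	8-6-22	0.94	0
8	82	21-31-30	253	Cluster 8	33	6-13-14	0.90	1
8	82	21-31-30	253	Cluster 9	9	2-3-4	1.00	1
8	82	21-31-30	253	Cluster 10	40	13-15-12	0.97	1
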