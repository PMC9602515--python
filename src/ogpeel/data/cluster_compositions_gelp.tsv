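cluster	n_total	n_per_species	positions
Cluster 1	47	2-6-5-7-6-4-5-9-3	231
Cluster 2	37	3-5-4-4-4-4-4-4-5	217
Cluster 3	30	1-2-3-2-6-8-1-5-2	254
Cluster 4	253	17-26-35-54-22-23-25-25-27	169
Sub-cluster 4X	50	5-2-4-2-10-9-10-4-4	334
Sub-cluster 4Y	149	9-20-24-44-5-6-8-14-19	220
Cluster 5	60	10-2-0-0-8-12-10-11-7	284
Cluster 6	35	4-3-4-3-3-5-6-4-3	319
Cluster 7	103	8-6-8-7-22-14-15-15-8	240
Cluster 8	129	6-13-12-18-14-13-11-33-9	262
Cluster 8X	84	3-6-7-10-10-7-6-29-6	275
Cluster 8X1	29	2-1-2-3-3-2-4-8-4	295
Cluster 8X2	55	1-5-5-7-7-5-2-21-2	279
Cluster 9	32	2-3-4-3-4-3-3-5-5	312
Cluster 10	129	13-15-20-24-12-15-11-9-10	213
Cluster 10X	33	1-4-5-5-4-3-3-4-4	334
Cluster 10Y	37	3-6-10-10-2-3-2-0-1	249
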