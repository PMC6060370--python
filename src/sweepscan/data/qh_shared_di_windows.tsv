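chrom	pos	cutting	halter	racing	reining	western_pleasure	working_cow
1	13685246	0	0	1	1	0	0
1	119564500	0	1	1	0	0	0
1	119676493	0	1	1	0	0	0
1	161715511	0	1	0	1	0	0
2	28112330	0	1	0	1	0	1
2	63922661	0	1	0	0	0	1
2	93844075	0	1	0	1	0	0
2	93904657	0	1	0	0	1	0
2	95577244	0	0	0	0	1	1
2	95962979	0	1	0	0	1	0
2	96425441	0	1	0	0	1	0
3	12705501	1	1	0	0	0	0
3	68445127	1	0	0	0	1	0
4	18376592	0	0	0	1	0	1
4	19475682	0	0	1	0	0	1
4	35285735	0	1	0	1	0	0
4	106747371	0	1	0	1	0	1
5	65517082	0	1	0	1	0	0
6	25394821	0	0	1	1	0	0
6	26913211	0	0	1	1	0	0
6	30595130	0	0	1	1	0	0
6	30637559	0	0	1	1	0	0
6	30686504	0	0	1	1	0	0
6	30705641	0	0	1	1	0	0
6	30724394	0	0	1	1	0	0
6	30753624	0	0	1	1	0	0
6	31086772	0	0	1	0	0	1
6	31334561	0	0	1	1	0	0
6	81474997	0	1	1	1	0	1
6	81534461	0	0	0	1	1	1
7	5529473	1	0	0	0	1	0
7	65654968	0	0	1	0	0	1
9	69646156	0	0	1	1	0	0
9	70735787	0	0	1	1	0	0
9	70814115	1	0	0	1	0	0
10	23574776	1	0	0	0	1	1
10	23956861	1	0	1	0	1	0
10	24014382	0	0	0	0	1	1
10	66622713	0	0	1	1	0	1
10	71364970	0	1	0	0	1	0
10	83744000	0	1	0	1	0	0
11	3863250	1	1	0	0	0	0
11	35553211	0	1	0	1	0	0
11	36006028	0	1	0	1	0	0
11	38335749	1	1	0	0	0	0
16	24163505	0	0	1	1	0	0
17	15344171	1	0	0	0	0	1
18	19864538	0	0	1	0	0	1
18	50904645	1	0	0	0	0	1
20	12885496	0	0	1	1	0	0
20	25186056	0	0	0	0	1	1
20	35886068	0	1	0	1	0	0
25	6263862	0	1	0	0	1	0
25	6734228	0	0	1	0	0	1
25	14862570	0	0	0	1	1	0
28	14573111	1	0	0	0	0	1
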