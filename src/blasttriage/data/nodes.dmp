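1	|	1	|	no rank	|
131567	|	1	|	no rank	|
2	|	131567	|	superkingdom	|
2157	|	131567	|	superkingdom	|
2759	|	131567	|	superkingdom	|
1224	|	2	|	phylum	|
1236	|	1224	|	class	|
91347	|	1236	|	order	|
543	|	91347	|	family	|
561	|	543	|	genus	|
562	|	561	|	species	|
620	|	543	|	genus	|
622	|	620	|	species	|
570	|	543	|	genus	|
573	|	570	|	species	|
286	|	1236	|	genus	|
287	|	286	|	species	|
1239	|	2	|	phylum	|
91061	|	1239	|	class	|
1385	|	91061	|	order	|
1386	|	1385	|	genus	|
1423	|	1386	|	species	|
1279	|	1385	|	genus	|
1280	|	1279	|	species	|
201174	|	2	|	phylum	|
1760	|	201174	|	class	|
1883	|	1760	|	genus	|
1902	|	1883	|	species	|
28890	|	2157	|	phylum	|
2184	|	28890	|	genus	|
2188	|	2184	|	species	|
33208	|	2759	|	kingdom	|
7711	|	33208	|	phylum	|
40674	|	7711	|	class	|
9443	|	40674	|	order	|
9605	|	9443	|	genus	|
9606	|	9605	|	species	|
10088	|	40674	|	genus	|
10090	|	10088	|	species	|
7954	|	7711	|	genus	|
7955	|	7954	|	species	|
6656	|	33208	|	phylum	|
50557	|	6656	|	class	|
7215	|	50557	|	genus	|
7227	|	7215	|	species	|
4751	|	2759	|	kingdom	|
4890	|	4751	|	phylum	|
4891	|	4890	|	class	|
4930	|	4891	|	genus	|
4932	|	4930	|	species	|
5052	|	4890	|	genus	|
5061	|	5052	|	species	|
33090	|	2759	|	kingdom	|
35493	|	33090	|	phylum	|
3701	|	35493	|	genus	|
3702	|	3701	|	species	|
4527	|	35493	|	genus	|
4530	|	4527	|	species	|
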