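1	|	root	|		|	scientific name	|
131567	|	cellular organisms	|		|	scientific name	|
2	|	Bacteria	|		|	scientific name	|
2	|	eubacteria	|		|	synonym	|
2157	|	Archaea	|		|	scientific name	|
2759	|	Eukaryota	|		|	scientific name	|
1224	|	Proteobacteria	|		|	scientific name	|
1236	|	Gammaproteobacteria	|		|	scientific name	|
91347	|	Enterobacterales	|		|	scientific name	|
543	|	Enterobacteriaceae	|		|	scientific name	|
561	|	Escherichia	|		|	scientific name	|
562	|	Escherichia coli	|		|	scientific name	|
620	|	Shigella	|		|	scientific name	|
622	|	Shigella dysenteriae	|		|	scientific name	|
570	|	Klebsiella	|		|	scientific name	|
573	|	Klebsiella pneumoniae	|		|	scientific name	|
286	|	Pseudomonas	|		|	scientific name	|
287	|	Pseudomonas aeruginosa	|		|	scientific name	|
1239	|	Firmicutes	|		|	scientific name	|
91061	|	Bacilli	|		|	scientific name	|
1385	|	Bacillales	|		|	scientific name	|
1386	|	Bacillus	|		|	scientific name	|
1423	|	Bacillus subtilis	|		|	scientific name	|
1279	|	Staphylococcus	|		|	scientific name	|
1280	|	Staphylococcus aureus	|		|	scientific name	|
201174	|	Actinobacteria	|		|	scientific name	|
1760	|	Actinomycetia	|		|	scientific name	|
1883	|	Streptomyces	|		|	scientific name	|
1902	|	Streptomyces coelicolor	|		|	scientific name	|
28890	|	Euryarchaeota	|		|	scientific name	|
2184	|	Methanococcus	|		|	scientific name	|
2188	|	Methanococcus voltae	|		|	scientific name	|
33208	|	Metazoa	|		|	scientific name	|
7711	|	Chordata	|		|	scientific name	|
40674	|	Mammalia	|		|	scientific name	|
9443	|	Primates	|		|	scientific name	|
9605	|	Homo	|		|	scientific name	|
9606	|	Homo sapiens	|		|	scientific name	|
10088	|	Mus	|		|	scientific name	|
10090	|	Mus musculus	|		|	scientific name	|
7954	|	Danio	|		|	scientific name	|
7955	|	Danio rerio	|		|	scientific name	|
6656	|	Arthropoda	|		|	scientific name	|
50557	|	Insecta	|		|	scientific name	|
7215	|	Drosophila	|		|	scientific name	|
7227	|	Drosophila melanogaster	|		|	scientific name	|
4751	|	Fungi	|		|	scientific name	|
4890	|	Ascomycota	|		|	scientific name	|
4891	|	Saccharomycetes	|		|	scientific name	|
4930	|	Saccharomyces	|		|	scientific name	|
4932	|	Saccharomyces cerevisiae	|		|	scientific name	|
5052	|	Aspergillus	|		|	scientific name	|
5061	|	Aspergillus niger	|		|	scientific name	|
33090	|	Viridiplantae	|		|	scientific name	|
35493	|	Streptophyta	|		|	scientific name	|
3701	|	Arabidopsis	|		|	scientific name	|
3702	|	Arabidopsis thaliana	|		|	scientific name	|
4527	|	Oryza	|		|	scientific name	|
4530	|	Oryza sativa	|		|	scientific name	|
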