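Node 1	Action	Node 2	Node 1 type	Node 2 type	UniProt ID 1	UniProt ID 2	PMID	Class	Evidence tag
Spg1	->	Cdc7	protein	protein	Q09771	P41891	8978672, 9490631	S	synthetic fixture row: the kinase Cdc7 associates with the signaling GTPase Spg1
Byr4-Cdc16	-|	Spg1	complex	protein		Q09771	9422735	U	synthetic fixture row: bipartite GAP inactivates the GTPase
Plo1	->	Spg1	protein	protein	P50528	Q09771	9990855	I	synthetic fixture row: polo kinase acts upstream of the SIN
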