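pattern_type	pattern	canonical_label
value	homo sapiens	Homo sapiens
value	human	Homo sapiens
value	mus musculus	Mus musculus
value	house mouse	Mus musculus
value	rattus norvegicus	Rattus norvegicus
value	danio rerio	Danio rerio
value	zebrafish	Danio rerio
value	gallus gallus	Gallus gallus
value	parus major	Parus major
value	glycine max	Glycine max
value	sus scrofa	Sus scrofa
value	bos taurus	Bos taurus
value	canis lupus familiaris	Canis lupus familiaris
value	macaca mulatta	Macaca mulatta
value	pan troglodytes	Pan troglodytes
value	ovis aries	Ovis aries
value	oryctolagus cuniculus	Oryctolagus cuniculus
value	equus caballus	Equus caballus
value	drosophila melanogaster	Drosophila melanogaster
value	caenorhabditis elegans	Caenorhabditis elegans
value	saccharomyces cerevisiae	Saccharomyces cerevisiae
value	arabidopsis thaliana	Arabidopsis thaliana
value	escherichia coli	Escherichia coli
value	oryza sativa	Oryza sativa
value	zea mays	Zea mays
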