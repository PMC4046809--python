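taxon	lineage
Monosiga	Eukaryota;Choanoflagellida
Salpingoeca	Eukaryota;Choanoflagellida
Homo	Eukaryota;Metazoa;Chordata
Drosophila	Eukaryota;Metazoa;Arthropoda
Nematostella	Eukaryota;Metazoa;Cnidaria
Saccharomyces	Eukaryota;Fungi;Ascomycota
Neurospora	Eukaryota;Fungi;Ascomycota
Dictyostelium	Eukaryota;Amoebozoa
Entamoeba	Eukaryota;Amoebozoa;Archamoebae
Naegleria	Eukaryota;Heterolobosea
Chlamydomonas	Eukaryota;Viridiplantae;Chlorophyta
Ostreococcus	Eukaryota;Viridiplantae;Chlorophyta;Mamiellales
Cyanidioschyzon	Eukaryota;Rhodophyta
Thalassiosira	Eukaryota;Stramenopiles;Bacillariophyta
Phytophthora	Eukaryota;Stramenopiles;Oomycetes
Emiliania	Eukaryota;Haptophyta
Tetrahymena	Eukaryota;Alveolata;Ciliophora
Escherichia	Bacteria;Proteobacteria
Bacillus	Bacteria;Firmicutes
Synechococcus	Bacteria;Cyanobacteria
Methanococcus	Archaea;Euryarchaeota
Haloferax	Archaea;Euryarchaeota
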