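# Default analysis-group definitions for a choanoflagellate focal genome.
# Each entry is a lineage-path prefix (semicolon-delimited, root first);
# a taxon is assigned to the group with the longest matching prefix.
# "Algae" is deliberately broad: every lineage with primary, secondary or
# tertiary plastids, plus oomycetes and ciliates (photosynthetic ancestry).
SELF:
  - Eukaryota;Choanoflagellida
KIN:
  - Eukaryota;Metazoa
  - Eukaryota;Fungi
PROKARYOTE:
  - Bacteria
  - Archaea
ALGA:
  - Eukaryota;Viridiplantae
  - Eukaryota;Glaucophyta
  - Eukaryota;Rhodophyta
  - Eukaryota;Alveolata
  - Eukaryota;Cryptophyta
  - Eukaryota;Euglenida
  - Eukaryota;Haptophyta
  - Eukaryota;Chlorarachniophyta
  - Eukaryota;Stramenopiles
  - Eukaryota;Stramenopiles;Oomycetes
  - Eukaryota;Alveolata;Ciliophora
OTHER_EUK:
  - Eukaryota
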