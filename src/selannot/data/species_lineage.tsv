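# Species -> lineage mapping used by `selannot lineage` when no explicit
# lineage is given.  Editable: add one tab-separated row per species.
# Lineage labels must match the lineage column of the expectation table.
Homo sapiens	placentals
Mus musculus	placentals
Rattus norvegicus	placentals
Sus scrofa	placentals
Bos taurus	placentals
Canis lupus familiaris	placentals
Monodelphis domestica	marsupials
Ornithorhynchus anatinus	monotremes
Gallus gallus	birds
Taeniopygia guttata	birds
Anolis carolinensis	reptiles
Chelonia mydas	reptiles
Xenopus tropicalis	amphibians
Danio rerio	teleost_fish
Oryzias latipes	teleost_fish
Takifugu rubripes	teleost_fish
Lepisosteus oculatus	holostean_fish
Callorhinchus milii	cartilaginous_fish
Petromyzon marinus	cyclostomes
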