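code	lineage	name
AMBTC	outgroup	Amborella trichopoda
PHODA	monocot	Phoenix dactylifera
MUSAC	monocot	Musa acuminata
ORYSA	monocot	Oryza sativa
VITVI	dicot	Vitis vinifera
PRUMU	dicot	Prunus mume
THECC	dicot	Theobroma cacao
ARATH	dicot	Arabidopsis thaliana
COFCA	dicot	Coffea canephora
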