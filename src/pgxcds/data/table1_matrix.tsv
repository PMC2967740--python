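drug	pathway_evidence	variant_evidence	genotype_data	phenotype_data	clinical_pgx_section
Abacavir		x			x
Atomoxetine
Atorvastatin	x	x			x
Azathioprine		x	x	x	x
Busulfan
Capecitabine		x
Carbamazepine		x			x
Celecoxib	x	x
Cetuximab	x				x
Clopidogrel	x	x			x
Codeine sulfate	x	x
Dasatinib					x
Erlotinib	x	x
Fluoxetine HCL	x	x		x
Imatinib mesylate	x	x			x
Irinotecan	x	x	x	x	x
Isoniazid	x
Lenalidomide
Maraviroc
Nilotinib
Panitumumab					x
Prasugrel
Primaquine
Pyrazinamide	x
Rasburicase					x
Rifampin	x	x	x	x
Trastuzumab		x			x
Valproic acid	x				x
Voriconazole
Warfarin	x	x	x	x	x
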