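# ILLUSTRATIVE drug-class membership lists (class_id <TAB> drug).
# Not clinically authoritative; substitute institutional lists as needed.
strong_cyp2d6_inhibitors	paroxetine
strong_cyp2d6_inhibitors	fluoxetine hcl
strong_cyp2d6_inhibitors	quinidine
strong_cyp2d6_inhibitors	bupropion
cyp2d6_substrates	atomoxetine
cyp2d6_substrates	codeine sulfate
cyp2d6_substrates	tamoxifen
cyp2d6_substrates	metoprolol
cyp2d6_substrates	nortriptyline
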