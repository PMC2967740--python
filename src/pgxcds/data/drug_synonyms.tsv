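# alias <TAB> canonical generic name
gleevec	imatinib mesylate
plavix	clopidogrel
prozac	fluoxetine hcl
strattera	atomoxetine
celebrex	celecoxib
coumadin	warfarin
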