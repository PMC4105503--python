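species	gene_a	gene_b
Gmax	GmHsf-09	GmHsf-34
Gmax	GmHsf-18	GmHsf-24
Gmax	GmHsf-18	GmHsf-46
Gmax	GmHsf-21	GmHsf-45
Ljaponicus	LjHsf-06	LjHsf-11
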