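lineage	n_groups	single_groups	pair_groups	absent_groups
Ljaponicus	17	9	1	7
Mtruncatula	17	11	2	4
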