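disease_1	disease_2	n_shared_genes	shared_genes
DIS00	DIS09	10	G0059,G0060,G0066,G0115,G0139,G0158,G0187,G0399,G0438,G0443
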