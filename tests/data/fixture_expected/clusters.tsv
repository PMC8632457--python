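cluster	threshold	members	shared_genes
1	0.3	DIS00,DIS03,DIS06,DIS09	G0059,G0066,G0115,G0438,G0443
2	0.3	DIS01,DIS04,DIS07,DIS10	G0013,G0030,G0100,G0220,G0391,G0411
3	0.3	DIS02,DIS05,DIS08,DIS11	G0197,G0217,G0242,G0358,G0372,G0379,G0404
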