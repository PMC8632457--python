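DIS00	0
DIS01	1
DIS02	2
DIS03	0
DIS04	1
DIS05	2
DIS06	0
DIS07	1
DIS08	2
DIS09	0
DIS10	1
DIS11	2
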