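node	node_type	degree
DIS00	disease	16
DIS09	disease	16
G0040	gene	1
G0059	gene	2
G0060	gene	2
G0066	gene	2
G0115	gene	2
G0139	gene	2
G0158	gene	2
G0171	gene	1
G0187	gene	2
G0190	gene	1
G0192	gene	1
G0247	gene	1
G0333	gene	1
G0345	gene	1
G0356	gene	1
G0399	gene	2
G0427	gene	1
G0430	gene	1
G0438	gene	2
G0443	gene	2
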