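source	target	edge_type
DIS00	G0040	association
DIS00	G0059	association
DIS00	G0060	association
DIS00	G0066	association
DIS00	G0115	association
DIS00	G0139	association
DIS00	G0158	association
DIS00	G0187	association
DIS00	G0333	association
DIS00	G0345	association
DIS00	G0399	association
DIS00	G0427	association
DIS00	G0430	association
DIS00	G0438	association
DIS00	G0443	association
DIS09	G0059	association
DIS09	G0060	association
DIS09	G0066	association
DIS09	G0115	association
DIS09	G0139	association
DIS09	G0158	association
DIS09	G0171	association
DIS09	G0187	association
DIS09	G0190	association
DIS09	G0192	association
DIS09	G0247	association
DIS09	G0356	association
DIS09	G0399	association
DIS09	G0438	association
DIS09	G0443	association
DIS00	DIS09	similarity
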