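rank	disease_1	disease_2	score
1	DIS00	DIS03	0.844846809
2	DIS03	DIS06	0.834387655
3	DIS02	DIS05	0.823837446
4	DIS04	DIS07	0.822897518
5	DIS01	DIS07	0.822679880
6	DIS05	DIS08	0.820226163
7	DIS02	DIS08	0.819067530
8	DIS00	DIS06	0.816797060
9	DIS01	DIS04	0.815110442
10	DIS04	DIS10	0.808379042
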