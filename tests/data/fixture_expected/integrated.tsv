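disease	DIS00	DIS01	DIS02	DIS03	DIS04	DIS05	DIS06	DIS07	DIS08	DIS09	DIS10	DIS11
DIS00	1	-0	-0	0.84484680878	-0	-0	0.816797059593	-0	-0	0.798010854894	-0	-0
DIS01	-0	1	-0	-0	0.815110442488	-0	-0	0.822679880218	-0	-0	0.791593161439	-0
DIS02	-0	-0	1	-0	-0	0.823837446399	-0	-0	0.819067529856	-0	-0	0.789169107161
DIS03	0.84484680878	-0	-0	1	-0	-0	0.834387655094	-0	-0	0.802796731335	-0	-0
DIS04	-0	0.815110442488	-0	-0	1	-0	-0	0.822897517841	-0	-0	0.808379042257	-0
DIS05	-0	-0	0.823837446399	-0	-0	1	-0	-0	0.820226162727	-0	-0	0.79850174031
DIS06	0.816797059593	-0	-0	0.834387655094	-0	-0	1	-0	-0	0.793852649227	-0	-0
DIS07	-0	0.822679880218	-0	-0	0.822897517841	-0	-0	1	-0	-0	0.796479065566	-0
DIS08	-0	-0	0.819067529856	-0	-0	0.820226162727	-0	-0	1	-0	-0	0.790417994371
DIS09	0.798010854894	-0	-0	0.802796731335	-0	-0	0.793852649227	-0	-0	1	-0	-0
DIS10	-0	0.791593161439	-0	-0	0.808379042257	-0	-0	0.796479065566	-0	-0	1	-0
DIS11	-0	-0	0.789169107161	-0	-0	0.79850174031	-0	-0	0.790417994371	-0	-0	1
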