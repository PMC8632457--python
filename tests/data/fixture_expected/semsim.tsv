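disease	DIS00	DIS01	DIS02	DIS03	DIS04	DIS05	DIS06	DIS07	DIS08	DIS09	DIS10	DIS11
DIS00	1	-0	-0	0.717103470768	-0	-0	0.717103470768	-0	-0	0.646209524602	-0	-0
DIS01	-0	1	-0	-0	0.717103470768	-0	-0	0.717103470768	-0	-0	0.646209524602	-0
DIS02	-0	-0	1	-0	-0	0.742720224459	-0	-0	0.742720224459	-0	-0	0.646209524602
DIS03	0.717103470768	-0	-0	1	-0	-0	0.717103470768	-0	-0	0.646209524602	-0	-0
DIS04	-0	0.717103470768	-0	-0	1	-0	-0	0.717103470768	-0	-0	0.646209524602	-0
DIS05	-0	-0	0.742720224459	-0	-0	1	-0	-0	0.742720224459	-0	-0	0.646209524602
DIS06	0.717103470768	-0	-0	0.717103470768	-0	-0	1	-0	-0	0.646209524602	-0	-0
DIS07	-0	0.717103470768	-0	-0	0.717103470768	-0	-0	1	-0	-0	0.646209524602	-0
DIS08	-0	-0	0.742720224459	-0	-0	0.742720224459	-0	-0	1	-0	-0	0.646209524602
DIS09	0.646209524602	-0	-0	0.646209524602	-0	-0	0.646209524602	-0	-0	1	-0	-0
DIS10	-0	0.646209524602	-0	-0	0.646209524602	-0	-0	0.646209524602	-0	-0	1	-0
DIS11	-0	-0	0.646209524602	-0	-0	0.646209524602	-0	-0	0.646209524602	-0	-0	1
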