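disease	DIS00	DIS01	DIS02	DIS03	DIS04	DIS05	DIS06	DIS07	DIS08	DIS09	DIS10	DIS11
DIS00	1	0.0453159087197	0	0.845865682691	0.0592722912988	0	0.773338589869	0.0453159087197	0.0383587911097	0.786844965128	0.00634428193681	0
DIS01	0.0453159087197	1	0	0.00634428193681	0.755852076306	0	0.00634428193681	0.777794768227	0	0.00634428193681	0.768755238548	0
DIS02	0	0	1	0.0327592745343	0	0.753718428347	0.151185803703	0.0666666666667	0.780477647998	0	0	0.768345405664
DIS03	0.845865682691	0.00634428193681	0.0327592745343	1	0.0752668121247	0.0327592745343	0.812569703124	0.00634428193681	0.071118065644	0.802935284391	0.0573941377216	0.0664355577425
DIS04	0.0592722912988	0.755852076306	0	0.0752668121247	1	0.0648555751169	0.0752668121247	0.778477521894	0.0648555751169	0.0400231255493	0.821143490809	0.0648555751169
DIS05	0	0	0.753718428347	0.0327592745343	0.0648555751169	1	0.180477647998	0.0648555751169	0.776827170252	0	0.0648555751169	0.792821445718
DIS06	0.773338589869	0.00634428193681	0.151185803703	0.812569703124	0.0752668121247	0.180477647998	1	0.00634428193681	0.181548884507	0.783429565336	0.00634428193681	0.192812537647
DIS07	0.0453159087197	0.777794768227	0.0666666666667	0.00634428193681	0.778477521894	0.0648555751169	0.00634428193681	1	0.0648555751169	0.00634428193681	0.784337789267	0.0648555751169
DIS08	0.0383587911097	0	0.780477647998	0.071118065644	0.0648555751169	0.776827170252	0.181548884507	0.0648555751169	1	0.0383587911097	0.0648555751169	0.777378052914
DIS09	0.786844965128	0.00634428193681	0	0.802935284391	0.0400231255493	0	0.783429565336	0.00634428193681	0.0383587911097	1	0.00634428193681	0
DIS10	0.00634428193681	0.768755238548	0	0.0573941377216	0.821143490809	0.0648555751169	0.00634428193681	0.784337789267	0.0648555751169	0.00634428193681	1	0.0648555751169
DIS11	0	0	0.768345405664	0.0664355577425	0.0648555751169	0.792821445718	0.192812537647	0.0648555751169	0.777378052914	0	0.0648555751169	1
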