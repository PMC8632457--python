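DIS00	T:R.0.0.0.0
DIS01	T:R.1.0.0.0
DIS02	T:R.2.0.0.0
DIS03	T:R.0.0.0.1
DIS04	T:R.1.0.0.1
DIS05	T:R.2.0.0.1
DIS06	T:R.0.0.0.2
DIS07	T:R.1.0.0.2
DIS08	T:R.2.0.0.2
DIS09	T:R.0.0.1.0
DIS10	T:R.1.0.1.0
DIS11	T:R.2.0.1.0
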