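((DIS09:0.2897239465,(DIS06:0.2476934277,(DIS00:0.2201757461,DIS03:0.2201757461):0.02751768166):0.04203051879):2.150405114,((DIS10:0.2863739431,(DIS01:0.2564743126,(DIS04:0.2508574978,DIS07:0.2508574978):0.005616814782):0.02989963047):2.146743849,(DIS11:0.2959659674,(DIS08:0.2551587417,(DIS02:0.2493089069,DIS05:0.2493089069):0.005849834817):0.04080722571):2.137151825):0.007011268424);
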