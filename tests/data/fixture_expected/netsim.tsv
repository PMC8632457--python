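disease	DIS00	DIS01	DIS02	DIS03	DIS04	DIS05	DIS06	DIS07	DIS08	DIS09	DIS10	DIS11
DIS00	1	0.997550820326	0.993004968818	0.994147154279	0.999242299469	0.994788923011	0.982632197354	0.998804296654	0.97857434319	0.999456441804	0.99352219674	0.999051348712
DIS01	0.997550820326	1	0.982593106132	0.997485285254	0.99915009968	0.98533997933	0.989929618307	0.998264866144	0.989096984847	0.998642713768	0.998492157146	0.997179476695
DIS02	0.993004968818	0.982593106132	1	0.975687483166	0.98899899679	0.998826833342	0.956233735504	0.987522534633	0.947923759625	0.989107159545	0.973258599598	0.989875042006
DIS03	0.994147154279	0.997485285254	0.975687483166	1	0.994812656072	0.981825913536	0.996921953959	0.998019407034	0.994432663051	0.997155499204	0.999326339958	0.996845983548
DIS04	0.999242299469	0.99915009968	0.98899899679	0.994812656072	1	0.990346950308	0.984154076985	0.998181129799	0.982276366615	0.99903262529	0.995526276233	0.997744213398
DIS05	0.994788923011	0.98533997933	0.998826833342	0.981825913536	0.990346950308	1	0.965601470258	0.991562799565	0.956425609772	0.992291085026	0.978408182607	0.993753924799
DIS06	0.982632197354	0.989929618307	0.956233735504	0.996921953959	0.984154076985	0.965601470258	1	0.9902056578	0.998414481875	0.988203490066	0.996048128817	0.988076296276
DIS07	0.998804296654	0.998264866144	0.987522534633	0.998019407034	0.998181129799	0.991562799565	0.9902056578	1	0.986101904518	0.999839246751	0.99688853571	0.999816290393
DIS08	0.97857434319	0.989096984847	0.947923759625	0.994432663051	0.982276366615	0.956425609772	0.998414481875	0.986101904518	1	0.984471246933	0.995547345376	0.983025595237
DIS09	0.999456441804	0.998642713768	0.989107159545	0.997155499204	0.99903262529	0.992291085026	0.988203490066	0.999839246751	0.984471246933	1	0.996416618618	0.999692244988
DIS10	0.99352219674	0.998492157146	0.973258599598	0.999326339958	0.995526276233	0.978408182607	0.996048128817	0.99688853571	0.995547345376	0.996416618618	1	0.995209134061
DIS11	0.999051348712	0.997179476695	0.989875042006	0.996845983548	0.997744213398	0.993753924799	0.988076296276	0.999816290393	0.983025595237	0.999692244988	0.995209134061	1
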