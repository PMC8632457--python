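DIS00	G0040
DIS00	G0059
DIS00	G0060
DIS00	G0066
DIS00	G0115
DIS00	G0139
DIS00	G0158
DIS00	G0187
DIS00	G0333
DIS00	G0345
DIS00	G0399
DIS00	G0427
DIS00	G0430
DIS00	G0438
DIS00	G0443
DIS01	G0009
DIS01	G0013
DIS01	G0030
DIS01	G0075
DIS01	G0100
DIS01	G0129
DIS01	G0220
DIS01	G0233
DIS01	G0257
DIS01	G0259
DIS01	G0303
DIS01	G0391
DIS01	G0411
DIS01	G0447
DIS01	G0481
DIS02	G0015
DIS02	G0105
DIS02	G0120
DIS02	G0127
DIS02	G0197
DIS02	G0217
DIS02	G0242
DIS02	G0358
DIS02	G0372
DIS02	G0379
DIS02	G0384
DIS02	G0404
DIS02	G0444
DIS02	G0475
DIS02	G0489
DIS03	G0040
DIS03	G0052
DIS03	G0059
DIS03	G0066
DIS03	G0115
DIS03	G0158
DIS03	G0187
DIS03	G0210
DIS03	G0247
DIS03	G0304
DIS03	G0345
DIS03	G0399
DIS03	G0435
DIS03	G0438
DIS03	G0443
DIS04	G0009
DIS04	G0013
DIS04	G0030
DIS04	G0038
DIS04	G0100
DIS04	G0121
DIS04	G0129
DIS04	G0144
DIS04	G0220
DIS04	G0233
DIS04	G0380
DIS04	G0387
DIS04	G0391
DIS04	G0411
DIS04	G0498
DIS05	G0015
DIS05	G0065
DIS05	G0120
DIS05	G0197
DIS05	G0217
DIS05	G0242
DIS05	G0248
DIS05	G0349
DIS05	G0358
DIS05	G0363
DIS05	G0372
DIS05	G0379
DIS05	G0404
DIS05	G0419
DIS05	G0489
DIS06	G0040
DIS06	G0059
DIS06	G0060
DIS06	G0066
DIS06	G0115
DIS06	G0139
DIS06	G0192
DIS06	G0247
DIS06	G0345
DIS06	G0350
DIS06	G0379
DIS06	G0395
DIS06	G0435
DIS06	G0438
DIS06	G0443
DIS07	G0013
DIS07	G0030
DIS07	G0100
DIS07	G0129
DIS07	G0144
DIS07	G0220
DIS07	G0233
DIS07	G0257
DIS07	G0262
DIS07	G0303
DIS07	G0380
DIS07	G0384
DIS07	G0391
DIS07	G0396
DIS07	G0411
DIS08	G0005
DIS08	G0015
DIS08	G0065
DIS08	G0127
DIS08	G0195
DIS08	G0197
DIS08	G0217
DIS08	G0242
DIS08	G0248
DIS08	G0358
DIS08	G0372
DIS08	G0379
DIS08	G0404
DIS08	G0475
DIS08	G0487
DIS09	G0059
DIS09	G0060
DIS09	G0066
DIS09	G0115
DIS09	G0139
DIS09	G0158
DIS09	G0171
DIS09	G0187
DIS09	G0190
DIS09	G0192
DIS09	G0247
DIS09	G0356
DIS09	G0399
DIS09	G0438
DIS09	G0443
DIS10	G0009
DIS10	G0013
DIS10	G0030
DIS10	G0100
DIS10	G0116
DIS10	G0131
DIS10	G0144
DIS10	G0193
DIS10	G0220
DIS10	G0257
DIS10	G0259
DIS10	G0303
DIS10	G0380
DIS10	G0391
DIS10	G0411
DIS11	G0065
DIS11	G0070
DIS11	G0071
DIS11	G0127
DIS11	G0146
DIS11	G0197
DIS11	G0217
DIS11	G0242
DIS11	G0248
DIS11	G0281
DIS11	G0358
DIS11	G0372
DIS11	G0379
DIS11	G0404
DIS11	G0489
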