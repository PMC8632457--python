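T:R.0.0.0.0	G0040
T:R.0.0.0.0	G0059
T:R.0.0.0.0	G0060
T:R.0.0.0.0	G0066
T:R.0.0.0.0	G0115
T:R.0.0.0.0	G0139
T:R.0.0.0.0	G0158
T:R.0.0.0.0	G0187
T:R.0.0.0.0	G0333
T:R.0.0.0.0	G0345
T:R.0.0.0.0	G0399
T:R.0.0.0.0	G0427
T:R.0.0.0.0	G0430
T:R.0.0.0.0	G0438
T:R.0.0.0.0	G0443
T:R.0.0.0.1	G0040
T:R.0.0.0.1	G0052
T:R.0.0.0.1	G0059
T:R.0.0.0.1	G0066
T:R.0.0.0.1	G0115
T:R.0.0.0.1	G0158
T:R.0.0.0.1	G0187
T:R.0.0.0.1	G0210
T:R.0.0.0.1	G0247
T:R.0.0.0.1	G0304
T:R.0.0.0.1	G0345
T:R.0.0.0.1	G0399
T:R.0.0.0.1	G0435
T:R.0.0.0.1	G0438
T:R.0.0.0.1	G0443
T:R.0.0.0.2	G0040
T:R.0.0.0.2	G0059
T:R.0.0.0.2	G0060
T:R.0.0.0.2	G0066
T:R.0.0.0.2	G0115
T:R.0.0.0.2	G0139
T:R.0.0.0.2	G0192
T:R.0.0.0.2	G0247
T:R.0.0.0.2	G0345
T:R.0.0.0.2	G0350
T:R.0.0.0.2	G0379
T:R.0.0.0.2	G0395
T:R.0.0.0.2	G0435
T:R.0.0.0.2	G0438
T:R.0.0.0.2	G0443
T:R.0.0.1.0	G0059
T:R.0.0.1.0	G0060
T:R.0.0.1.0	G0066
T:R.0.0.1.0	G0115
T:R.0.0.1.0	G0139
T:R.0.0.1.0	G0158
T:R.0.0.1.0	G0171
T:R.0.0.1.0	G0187
T:R.0.0.1.0	G0190
T:R.0.0.1.0	G0192
T:R.0.0.1.0	G0247
T:R.0.0.1.0	G0356
T:R.0.0.1.0	G0399
T:R.0.0.1.0	G0438
T:R.0.0.1.0	G0443
T:R.1.0.0.0	G0009
T:R.1.0.0.0	G0013
T:R.1.0.0.0	G0030
T:R.1.0.0.0	G0075
T:R.1.0.0.0	G0100
T:R.1.0.0.0	G0129
T:R.1.0.0.0	G0220
T:R.1.0.0.0	G0233
T:R.1.0.0.0	G0257
T:R.1.0.0.0	G0259
T:R.1.0.0.0	G0303
T:R.1.0.0.0	G0391
T:R.1.0.0.0	G0411
T:R.1.0.0.0	G0447
T:R.1.0.0.0	G0481
T:R.1.0.0.1	G0009
T:R.1.0.0.1	G0013
T:R.1.0.0.1	G0030
T:R.1.0.0.1	G0038
T:R.1.0.0.1	G0100
T:R.1.0.0.1	G0121
T:R.1.0.0.1	G0129
T:R.1.0.0.1	G0144
T:R.1.0.0.1	G0220
T:R.1.0.0.1	G0233
T:R.1.0.0.1	G0380
T:R.1.0.0.1	G0387
T:R.1.0.0.1	G0391
T:R.1.0.0.1	G0411
T:R.1.0.0.1	G0498
T:R.1.0.0.2	G0013
T:R.1.0.0.2	G0030
T:R.1.0.0.2	G0100
T:R.1.0.0.2	G0129
T:R.1.0.0.2	G0144
T:R.1.0.0.2	G0220
T:R.1.0.0.2	G0233
T:R.1.0.0.2	G0257
T:R.1.0.0.2	G0262
T:R.1.0.0.2	G0303
T:R.1.0.0.2	G0380
T:R.1.0.0.2	G0384
T:R.1.0.0.2	G0391
T:R.1.0.0.2	G0396
T:R.1.0.0.2	G0411
T:R.1.0.1.0	G0009
T:R.1.0.1.0	G0013
T:R.1.0.1.0	G0030
T:R.1.0.1.0	G0100
T:R.1.0.1.0	G0116
T:R.1.0.1.0	G0131
T:R.1.0.1.0	G0144
T:R.1.0.1.0	G0193
T:R.1.0.1.0	G0220
T:R.1.0.1.0	G0257
T:R.1.0.1.0	G0259
T:R.1.0.1.0	G0303
T:R.1.0.1.0	G0380
T:R.1.0.1.0	G0391
T:R.1.0.1.0	G0411
T:R.2.0.0.0	G0015
T:R.2.0.0.0	G0105
T:R.2.0.0.0	G0120
T:R.2.0.0.0	G0127
T:R.2.0.0.0	G0197
T:R.2.0.0.0	G0217
T:R.2.0.0.0	G0242
T:R.2.0.0.0	G0358
T:R.2.0.0.0	G0372
T:R.2.0.0.0	G0379
T:R.2.0.0.0	G0384
T:R.2.0.0.0	G0404
T:R.2.0.0.0	G0444
T:R.2.0.0.0	G0475
T:R.2.0.0.0	G0489
T:R.2.0.0.1	G0015
T:R.2.0.0.1	G0065
T:R.2.0.0.1	G0120
T:R.2.0.0.1	G0197
T:R.2.0.0.1	G0217
T:R.2.0.0.1	G0242
T:R.2.0.0.1	G0248
T:R.2.0.0.1	G0349
T:R.2.0.0.1	G0358
T:R.2.0.0.1	G0363
T:R.2.0.0.1	G0372
T:R.2.0.0.1	G0379
T:R.2.0.0.1	G0404
T:R.2.0.0.1	G0419
T:R.2.0.0.1	G0489
T:R.2.0.0.2	G0005
T:R.2.0.0.2	G0015
T:R.2.0.0.2	G0065
T:R.2.0.0.2	G0127
T:R.2.0.0.2	G0195
T:R.2.0.0.2	G0197
T:R.2.0.0.2	G0217
T:R.2.0.0.2	G0242
T:R.2.0.0.2	G0248
T:R.2.0.0.2	G0358
T:R.2.0.0.2	G0372
T:R.2.0.0.2	G0379
T:R.2.0.0.2	G0404
T:R.2.0.0.2	G0475
T:R.2.0.0.2	G0487
T:R.2.0.1.0	G0065
T:R.2.0.1.0	G0070
T:R.2.0.1.0	G0071
T:R.2.0.1.0	G0127
T:R.2.0.1.0	G0146
T:R.2.0.1.0	G0197
T:R.2.0.1.0	G0217
T:R.2.0.1.0	G0242
T:R.2.0.1.0	G0248
T:R.2.0.1.0	G0281
T:R.2.0.1.0	G0358
T:R.2.0.1.0	G0372
T:R.2.0.1.0	G0379
T:R.2.0.1.0	G0404
T:R.2.0.1.0	G0489
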