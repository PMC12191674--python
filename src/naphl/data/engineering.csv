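value
0.0251
0.0886
0.0891
0.2501
0.3113
0.3451
0.4763
0.5650
0.5671
0.6566
0.6748
0.6751
0.6753
0.7696
0.8375
0.8391
0.8425
0.8645
0.8851
0.9113
0.9120
0.9836
1.0483
1.0596
1.0773
1.1733
1.2570
1.2766
1.2985
1.3211
1.3503
1.3551
1.4595
1.4880
1.5728
1.5733
1.7083
1.7263
1.7460
1.7630
1.7746
1.8275
1.8375
1.8503
1.8808
1.8878
1.8881
1.9316
1.9558
2.0048
2.0408
2.0903
2.1093
2.1330
2.2100
2.2460
2.2878
2.3203
2.3470
2.3513
2.4951
2.5260
2.9911
3.0256
3.2678
3.4045
3.4846
3.7433
3.7455
3.9143
4.8073
5.4005
5.4435
5.5295
6.5541
9.0960
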