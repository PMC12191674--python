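value
0.0009
0.0040
0.0142
0.0221
0.0261
0.0418
0.0473
0.0834
0.1091
0.1252
0.1404
0.1498
0.1750
0.2031
0.2099
0.2168
0.2918
0.3465
0.4035
0.6143
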