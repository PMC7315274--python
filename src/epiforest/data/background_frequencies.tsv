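aa	frequency
A	0.070093
C	0.022998
D	0.047395
E	0.070993
F	0.036496
G	0.065793
H	0.026297
I	0.043396
K	0.057194
L	0.099690
M	0.021298
N	0.035896
P	0.063094
Q	0.047695
R	0.056394
S	0.083292
T	0.053595
V	0.059594
W	0.012199
Y	0.026597
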