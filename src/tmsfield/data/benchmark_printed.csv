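subject,simnibs_mean_s,realtime_mean_s,improvement_factor
1,6.62369,0.09607,66.67
2,8.10733,0.09891,81.97
3,7.53538,0.09138,82.46
4,7.08233,0.10517,67.34
5,7.16642,0.09653,74.24
6,7.67339,0.09448,81.21
7,8.45786,0.10163,83.22
8,7.64351,0.09645,79.25
9,8.08065,0.09769,82.71
10,7.50936,0.0842,89.18
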