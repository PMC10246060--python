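subject,machine,tool,seconds
1,apple_m1,simnibs,6.81622
1,cpu_i9,simnibs,6.43095
1,apple_m1,realtime,0.05539
1,cpu_i9,realtime,0.09607
2,apple_m1,simnibs,8.22622
2,cpu_i9,simnibs,7.98845
2,apple_m1,realtime,0.06353
2,cpu_i9,realtime,0.09891
3,apple_m1,simnibs,7.69764
3,cpu_i9,simnibs,7.37311
3,apple_m1,realtime,0.05733
3,cpu_i9,realtime,0.09138
4,apple_m1,simnibs,7.08191
4,cpu_i9,simnibs,7.08276
4,apple_m1,realtime,0.08974
4,cpu_i9,realtime,0.10517
5,apple_m1,simnibs,7.72296
5,cpu_i9,simnibs,6.60987
5,apple_m1,realtime,0.12807
5,cpu_i9,realtime,0.09652
6,apple_m1,simnibs,7.91043
6,cpu_i9,simnibs,7.43637
6,apple_m1,realtime,0.04735
6,cpu_i9,realtime,0.09448
7,apple_m1,simnibs,8.80702
7,cpu_i9,simnibs,8.10869
7,apple_m1,realtime,0.06146
7,cpu_i9,realtime,0.10163
8,apple_m1,simnibs,7.90561
8,cpu_i9,simnibs,7.3814
8,apple_m1,realtime,0.05229
8,cpu_i9,realtime,0.09645
9,apple_m1,simnibs,8.1296
9,cpu_i9,simnibs,8.0317
9,apple_m1,realtime,0.12303
9,cpu_i9,realtime,0.09769
10,apple_m1,simnibs,7.2251
10,cpu_i9,simnibs,7.7936
10,apple_m1,realtime,0.06049
10,cpu_i9,realtime,0.084202
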