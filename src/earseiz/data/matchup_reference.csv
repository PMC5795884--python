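pid,ear_channel,scalp_channel,coherence
1,LC-RC,Fz-Cz,0.96
1,LT-RT,F4-C4,0.99
1,LT-LC,F7-T3,0.99
1,RT-RC,T4-Sph2,0.89
2,LC-RC,T5-O1,0.91
2,LT-RT,T5-O1,0.92
2,LT-LC,T5-O1,0.93
2,RT-RC,T3-T5,0.79
3,LC-RC,Fp2-F8,0.81
3,LT-RT,Fp2-F8,0.82
3,LT-LC,T3-Sph1,0.75
3,RT-RC,C4-P4,0.81
4,LC-RC,F7-T3,0.95
4,LT-RT,F4-C4,0.96
4,LT-LC,F3-C3,0.93
4,RT-RC,F3-C3,0.74
5,LC-RC,T4-Sph2,0.88
5,LT-RT,T4-T6,0.85
5,LT-LC,Cz-Pz,0.74
5,RT-RC,T4-T6,0.81
6,LC-RC,Cz-Pz,0.81
6,LT-RT,T3-Sph1,0.73
6,LT-LC,C3-P3,0.79
6,RT-RC,Fp2-F8,0.78
7,LC-RC,T5-O1,0.71
7,LT-RT,T4-Sph2,0.68
7,LT-LC,C3-P3,0.73
7,RT-RC,P4-O2,0.87
8,LC-RC,T3-T5,0.70
8,LT-RT,T3-T5,0.73
8,LT-LC,F3-C3,0.76
8,RT-RC,T6-O2,0.79
9,LC-RC,P3-O1,0.91
9,LT-RT,F7-T3,0.95
9,LT-LC,T3-Sph1,0.95
9,RT-RC,T4-Sph2,0.92
10,LC-RC,Fp2-F4,0.94
10,LT-RT,Fp2-F4,0.87
10,LT-LC,Fp1-F3,0.85
10,RT-RC,P4-O2,0.81
11,LC-RC,Fp1-F7,0.77
11,LT-RT,T5-O1,0.77
11,LT-LC,P4-O2,0.71
11,RT-RC,Pz-O1,0.70
12,LC-RC,T5-O1,0.65
12,LT-RT,T6-O2,0.68
12,LT-LC,F3-C3,0.65
12,RT-RC,T4-Sph2,0.66
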