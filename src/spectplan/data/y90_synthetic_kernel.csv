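radius_mm,value
0.000000,1.00000000e+00
0.250000,9.04837418e-01
0.500000,8.18730753e-01
0.750000,7.40818221e-01
1.000000,6.70320046e-01
1.250000,6.06530660e-01
1.500000,5.48811636e-01
1.750000,4.96585304e-01
2.000000,4.49328964e-01
2.250000,4.06569660e-01
2.500000,3.67879441e-01
2.750000,3.32871084e-01
3.000000,3.01194212e-01
3.250000,2.72531793e-01
3.500000,2.46596964e-01
3.750000,2.23130160e-01
4.000000,2.01896518e-01
4.250000,1.82683524e-01
4.500000,1.65298888e-01
4.750000,1.49568619e-01
5.000000,1.35335283e-01
5.250000,1.22456428e-01
5.500000,1.10803158e-01
5.750000,1.00258844e-01
6.000000,9.07179533e-02
6.250000,8.20849986e-02
6.500000,7.42735782e-02
6.750000,6.72055127e-02
7.000000,6.08100626e-02
7.250000,5.50232201e-02
7.500000,4.97870684e-02
7.750000,4.50492024e-02
8.000000,4.07622040e-02
8.250000,3.68831674e-02
8.500000,3.33732700e-02
8.750000,3.01973834e-02
9.000000,2.73237224e-02
9.250000,2.47235265e-02
9.500000,2.23707719e-02
9.750000,2.02419114e-02
10.000000,1.83156389e-02
10.250000,1.65726754e-02
10.500000,1.49955768e-02
10.750000,1.35685590e-02
11.000000,1.22773399e-02
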