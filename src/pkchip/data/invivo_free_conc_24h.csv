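time_h,conc_nM,analyte
1,187.8,AZD0156
2,192.1,AZD0156
3,173.8,AZD0156
4,154.5,AZD0156
5,137.1,AZD0156
6,121.5,AZD0156
7,107.8,AZD0156
8,95.6,AZD0156
9,84.7,AZD0156
10,75.2,AZD0156
11,66.7,AZD0156
12,59.1,AZD0156
13,52.7,AZD0156
14,46.6,AZD0156
15,41.5,AZD0156
16,36.7,AZD0156
17,32.6,AZD0156
18,28.8,AZD0156
19,25.7,AZD0156
20,22.7,AZD0156
21,20.2,AZD0156
22,17.8,AZD0156
23,15.9,AZD0156
24,14.1,AZD0156
1,5.5,SN38
2,4.7,SN38
3,4.4,SN38
4,4.1,SN38
5,3.6,SN38
6,3.1,SN38
7,2.8,SN38
8,2.4,SN38
9,2.1,SN38
10,1.9,SN38
11,1.7,SN38
12,1.6,SN38
13,1.5,SN38
14,1.4,SN38
15,1.2,SN38
16,1.1,SN38
17,1.1,SN38
18,0.9,SN38
19,0.9,SN38
20,0.8,SN38
21,0.7,SN38
22,0.7,SN38
23,0.6,SN38
24,0.6,SN38
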