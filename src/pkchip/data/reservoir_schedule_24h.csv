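reservoir,start_h,duration_h,analyte,conc_nM
2,0,1,AZD0156,192
3,1,3,AZD0156,150
4,4,2,AZD0156,110
5,6,3,AZD0156,75
6,9,3,AZD0156,60
7,12,4,AZD0156,45
8,16,8,AZD0156,20
2,0,1,SN38,5.5
3,1,3,SN38,4.3
4,4,2,SN38,3.4
5,6,3,SN38,2.3
6,9,3,SN38,1.7
7,12,4,SN38,1.3
8,16,8,SN38,0.6
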