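volunteer,gm_t1,wm_t1,csf_t1
1,1250,897,4096
2,1527,829,4228
3,1331,832,4077
4,1592,996,4196
5,1823,974,4030
6,1497,915,4028
7,1479,859,3906
8,1388,967,3898
9,1255,858,3907
10,1286,875,4063
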