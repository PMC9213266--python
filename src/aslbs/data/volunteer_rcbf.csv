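volunteer,rcbf_regular,rcbf_adaptive
1,613,622
2,519,540
3,543,557
4,448,467
5,473,489
6,625,637
7,557,580
8,521,528
9,600,608
10,681,694
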