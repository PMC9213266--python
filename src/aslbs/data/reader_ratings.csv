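case,reader,category,rating
1,1,noise,1
1,2,noise,1
1,1,cortical_structures,0
1,2,cortical_structures,1
1,1,artifacts,-1
1,2,artifacts,0
2,1,noise,1
2,2,noise,1
2,1,cortical_structures,1
2,2,cortical_structures,1
2,1,artifacts,0
2,2,artifacts,0
3,1,noise,0
3,2,noise,0
3,1,cortical_structures,0
3,2,cortical_structures,0
3,1,artifacts,0
3,2,artifacts,0
4,1,noise,1
4,2,noise,1
4,1,cortical_structures,0
4,2,cortical_structures,1
4,1,artifacts,0
4,2,artifacts,0
5,1,noise,-1
5,2,noise,1
5,1,cortical_structures,1
5,2,cortical_structures,1
5,1,artifacts,0
5,2,artifacts,0
6,1,noise,1
6,2,noise,0
6,1,cortical_structures,0
6,2,cortical_structures,0
6,1,artifacts,0
6,2,artifacts,0
7,1,noise,1
7,2,noise,0
7,1,cortical_structures,1
7,2,cortical_structures,0
7,1,artifacts,0
7,2,artifacts,0
8,1,noise,1
8,2,noise,-1
8,1,cortical_structures,1
8,2,cortical_structures,-1
8,1,artifacts,0
8,2,artifacts,-1
9,1,noise,1
9,2,noise,0
9,1,cortical_structures,1
9,2,cortical_structures,0
9,1,artifacts,0
9,2,artifacts,0
10,1,noise,1
10,2,noise,0
10,1,cortical_structures,0
10,2,cortical_structures,0
10,1,artifacts,0
10,2,artifacts,0
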