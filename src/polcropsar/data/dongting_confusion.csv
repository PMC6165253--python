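class,Water,Rice1,Rice2,Watermelon,Lotus,Bare soil,Forest,Grass
Water,237449,0,0,0,35,1052,249,377
Rice1,5,152273,21550,9,3014,882,6381,1965
Rice2,124,44750,97382,13,392,1108,41935,13133
Watermelon,624,34,3,98113,68,13364,361,3812
Lotus,0,104,13,0,179632,0,270,1790
Bare soil,2732,591,98,8074,92,113877,384,3540
Forest,125,342,2715,0,50,81,106606,910
Grass,115,1797,508,463,4785,4363,12642,183418
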