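class,testing_pixels
Water,241174
Rice1,199891
Rice2,122269
Watermelon,106678
Lotus,188068
Bare soil,134727
Forest,168832
Grass,208945
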