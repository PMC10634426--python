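source,intercept,slope
Argento,17.7,19.5
Nielsen,55.94,13.38
Babaya,-128.8,38.07
Niwaha,-55.37,25.77
Zhou,-10.48,21.56
Munshi,34.69,17.19
Nathan,-46.7,28.7
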