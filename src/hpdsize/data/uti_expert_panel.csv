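expert_id,opinion
1,0.30
2,0.25
3,0.15
4,0.40
5,0.30
6,0.20
7,0.20
8,0.30
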