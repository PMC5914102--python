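zone,1,2,3,4
1,0.1,0.25,0.3,0.35
2,0.25,0.1,0.3,0.45
3,0.3,0.3,0.1,0.25
4,0.35,0.45,0.25,0.1
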