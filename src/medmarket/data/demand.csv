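zone,1,2,3,4
1,0,10,4,4
2,8,0,3,5
3,4,2,0,10
4,2,4,6,0
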