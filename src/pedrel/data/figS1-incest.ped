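1 0 0 1
2 0 0 2
3 1 2 2
4 1 2 1
5 1 3 1
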