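1 0 0 1
2 0 0 2
3 1 2 1
4 0 0 2
5 1 2 2
6 0 0 1
7 3 4 1
8 6 5 2
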