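1 0 0 1
2 0 0 2
3 0 0 1
4 0 0 2
5 1 2 1
6 3 4 2
7 1 4 1
8 3 2 2
9 5 6 1
10 7 8 2
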