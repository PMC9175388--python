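1 0 0 1 1
2 0 0 2 1
3 0 0 1 1
4 1 2 1 1
5 3 2 2 1
6 4 5 1 2
7 4 5 2 2
# status: 1 deceased
# status: 3 deceased
# status: 2 carrier
# status: 4 carrier
# status: 5 carrier
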