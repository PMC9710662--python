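DNA, M1_pos1 = 1-5\3
DNA, M1_pos2 = 2-5\3
DNA, M1_pos3 = 3-5\3
DNA, M2 = 6-8
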