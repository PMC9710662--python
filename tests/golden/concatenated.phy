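 3 8
A ACGTA???
B AC-TAGGT
C ?????GCT
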