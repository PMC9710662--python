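specimen_voucher	sequence_M1	sequence_M2
A	ACGTA	
B	AC-TA	GGT
C		GCT
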