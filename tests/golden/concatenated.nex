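#NEXUS
begin data;
dimensions ntax=3 nchar=8;
format datatype=dna missing=? gap=-;
matrix
A ACGTA???
B AC-TAGGT
C ?????GCT
;
end;
begin sets;
charset M1 = 1-5;
charset M2 = 6-8;
charset M1_pos1 = 1-5\3;
charset M1_pos2 = 2-5\3;
charset M1_pos3 = 3-5\3;
end;
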