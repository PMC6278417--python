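criterion,distance_OP,e_inter,e_hbond,n_residues
distance_OP,1,4,9,7
e_inter,1/4,1,7,4
e_hbond,1/9,1/7,1,1/4
n_residues,1/7,1/4,4,1
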