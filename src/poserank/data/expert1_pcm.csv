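criterion,distance_OP,e_inter,e_hbond,n_residues
distance_OP,1,5,9,7
e_inter,1/5,1,5,4
e_hbond,1/9,1/5,1,1/3
n_residues,1/7,1/4,3,1
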