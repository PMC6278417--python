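criterion,distance_OP,e_inter,e_hbond,n_residues
distance_OP,1,4.47,8.74,6.74
e_inter,0.22,1,5.44,3.72
e_hbond,0.11,0.18,1,0.29
n_residues,0.15,0.27,3.46,1
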