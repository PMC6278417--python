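ligand_id,distance_OP_A,E_inter_kcalmol,E_hbond_kcalmol,residues,n_residues,pct_reactivation_10min_10uM
isatin-O,4.03,-75.22,-1.60,Ser125,1,6.37
obidoxime,4.60,-122.48,-11.54,Ser203;Tyr124;Tyr337;Asp74,4,24.55
2-PAM,8.14,-87.18,-2.03,His447,1,4.13
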