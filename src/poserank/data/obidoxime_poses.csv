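ligand_id,run_id,pose_id,distance_OP_A,E_inter_kcalmol,E_hbond_kcalmol,residues,n_residues
obidoxime,1,Dock1,5.28,-123.99,-8.78,,4
obidoxime,2,Dock2,4.62,-125.10,-7.71,,3
obidoxime,3,Dock3,5.42,-103.54,-5.33,,2
obidoxime,4,Dock4,5.3,-111.45,-11.7,,3
obidoxime,5,Dock5,5.29,-122.32,-5.20,,3
obidoxime,6,Dock6,5.15,-122.76,-8.67,,4
obidoxime,7,Dock7,5.3,-118.75,-7.22,,3
obidoxime,8,Dock8,4.6,-122.48,-11.54,,4
obidoxime,9,Dock9,5.28,-121.38,-7.73,,3
obidoxime,10,Dock10,5.12,-111.4,-10.23,,2
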