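ligand_id,run_id,pose_id,distance_OP_A,E_inter_kcalmol,E_hbond_kcalmol,residues,n_residues
isatin-O,1,Dock1,5.19,-81.13,-4.92,,2
isatin-O,2,Dock2,4.50,-94.18,-2.65,,2
isatin-O,3,Dock3,3.75,-84.51,-0.6,,1
isatin-O,4,Dock4,5.76,-81.33,-7.76,,3
isatin-O,5,Dock5,4.68,-93.39,-2.53,,3
isatin-O,6,Dock6,5.44,-71.62,-2.25,,2
isatin-O,7,Dock7,3.76,-76.95,-2.18,,1
isatin-O,8,Dock8,4.50,-78.03,-0.96,,3
isatin-O,9,Dock9,4.60,-92.04,-3.77,,3
isatin-O,10,Dock10,4.50,-85.00,-0.24,,2
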