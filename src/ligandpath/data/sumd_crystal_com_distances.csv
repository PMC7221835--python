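# COM distances (A) between supervised-MD final ligand poses and crystal
# ligands of the same receptor, in the shared crystal frame.
ligand,reference,pdb_id,distance_A
THC,7DY,5u09,3.780
THC,8D0,5xr8,3.596
THC,8D3,5xra,3.595
THC,ZDG,5tgz,2.745
AEA,7DY,5u09,3.020
AEA,8D0,5xr8,3.211
AEA,8D3,5xra,3.463
AEA,ZDG,5tgz,2.759
S1P,ML5,3V2Y,7.920
S1P,ML5,3V2W,8.069
LPA,ON3,4z36,3.346
LPA,ON7,4z34,3.541
LPA,ON9,4z35,3.556
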