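residue_name,atom_name,radius,charge
*,N,1.55,-0.47
*,CA,1.70,0.07
*,C,1.70,0.51
*,O,1.52,-0.51
*,CB,1.70,0.0
*,OXT,1.52,-0.67
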