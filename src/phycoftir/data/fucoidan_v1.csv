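# library: fucoidan
# version: 1.0
# Marker bands of fucose-rich sulfated polysaccharides of brown algae.
code,center,window_lo,window_hi,types,shoulder_expected,specificity,weight,vibration
S=O,1220.0,1212.0,1228.0,fucoidan,false,specific,1.0,S=O of ester sulfate
O=S=O,1020.0,1012.0,1028.0,fucoidan,false,specific,1.0,symmetric O=S=O stretch
C-O-S,820.0,812.0,828.0,fucoidan,false,specific,1.0,C-O-S bend of sulfate on fucose
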