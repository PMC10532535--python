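# library: alginate
# version: 1.0
# Marker bands of alginates (mannuronic/guluronic acid copolymers) of brown algae.
code,center,window_lo,window_hi,types,shoulder_expected,specificity,weight,vibration
C-C/C=O,1600.0,1592.0,1608.0,alginate,false,specific,1.0,carboxylate C-C and C=O
C-OH,1410.0,1402.0,1418.0,alginate,false,specific,1.0,C-OH deformation
GulA-1081,1081.0,1073.0,1089.0,alginate,false,specific,1.0,guluronic acid ring
O=S=O,1026.0,1018.0,1034.0,alginate,false,specific,1.0,O=S=O / C-O stretch region
GulA-797,797.0,789.0,805.0,alginate,false,specific,1.0,guluronic acid anomeric
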