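# library: carrageenan
# version: 1.0
# Diagnostic mid-IR bands of iota/kappa/nu carrageenans, analysis window 800-1240 cm-1.
# Windows cover the positions observed on commercial standards and monthly extracts.
# weight < 1 marks bands whose assignment is ambiguous (sulfate band near 871 cm-1).
code,center,window_lo,window_hi,types,shoulder_expected,specificity,weight,vibration
S=O,1229.0,1214.0,1244.0,iota|kappa|nu,false,shared,1.0,S=O of ester sulfate
DA*,1070.0,1055.0,1078.0,iota|kappa,true,specific,1.0,C-O of 3;6-anhydrogalactose (shoulder)
G/D,972.5,966.0,979.0,iota|kappa|nu,false,shared,1.0,galactose backbone
DA,930.0,918.0,938.0,iota|kappa,false,specific,1.0,C-O of 3;6-anhydrogalactose
DA2S*,905.0,888.0,913.0,iota,true,specific,1.0,C-O-SO4 on C2 of 3;6-anhydrogalactose (shoulder)
G/D6S*,867.0,859.0,875.0,nu,true,specific,0.5,C-O-SO4 on C6 galactose (shoulder)
G4S,845.0,837.0,853.0,iota|kappa|nu,false,shared,1.0,C-O-SO4 on galactose C4
G/D2S,827.5,821.0,834.0,nu,false,specific,1.0,C-O-SO4 on galactose C2
G/D6S,817.5,811.0,824.0,nu,false,specific,1.0,C-O-SO4 on galactose C6
DA2S,805.0,797.0,813.0,iota,false,specific,1.0,C-O-SO4 on C2 of 3;6-anhydrogalactose
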