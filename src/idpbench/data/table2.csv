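name,n_residues,dev_scaling,dev_sop_idp,dev_bead_necklace,dev_martini
Hst5,24,1,-1,0,5
ACTR,71,0,-9,-5,-7
Nucleoporin,81,5,-4,-1,10
SH4-UD,85,1,-4,-8,-9
Sic1,90,-6,-12,-4,4
p53,93,8,3,10,-5
Proth. alpha,111,-10,3,18,-2
ERM TADn,122,-5,-18,-13,-20
hNHE1,131,1,-13,-9,-17
Alpha-synuclein,140,11,0,1,-19
An16,185,-7,-14,-14,-1
Osteopontin,273,6,-14,1,10
K19,99,-8,-15,-14,-18
K18,130,-1,-8,-6,-14
K17,143,11,4,8,-1
K10,167,9,-3,0,-9
K27,171,20,10,14,6
K16,174,15,7,12,3
K25,185,13,-3,-5,-17
K32,202,18,8,12,-3
K23,254,14,-3,-3,0
K44,283,15,-2,0,-2
hTau23,352,28,8,13,-1
hTau40,441,19,-3,-1,-37
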