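name,n_residues,rg_exp,rg_exp_err,rg_exp_alt,rg_exp_alt_err,rg_scaling,rg_sop_idp,rg_bead_necklace,rg_bead_necklace_alt,rg_martini,salt_mM,temperature_K,comment
Hst5,24,13.8,0.04,,,13.9,13.6,13.8,,14.4,,,
ACTR,71,26.3,,,,26.3,24.0,25.0,,24.3,,278,Exp. T = 278 K
Nucleoporin,81,27,4,,,28.5,25.9,26.8,,29.7,,296,Exp. T = 296 K
SH4-UD,85,29,0.4,,,29.3,27.8,26.6,,26.5,,277,Exp. T = 277 K
Sic1,90,32.1,0.8,,,30.3,28.4,30.7,,33.4,,,Bead necklace from Cragnell et al.
p53,93,28.7,,,,30.9,29.5,31.5,,27.4,,293,Exp. T = 293 K
Proth. alpha,111,37.9,0.9,,,34.3,39.1,72.3,44.6,37.2,0,296,"Exp. T = 296 K, 0 (150) mM NaCl; bead-necklace value in parentheses at 150 mM"
ERM TADn,122,38.1,0.7,,,36.3,31.4,33.0,,30.9,,293,Exp. T = 293 K
hNHE1,131,37.5,,,,37.8,32.5,34.1,,31.3,,278,Exp. T = 278 K
Alpha-synuclein,140,40.0,,35.5,0.5,39.3,35.4,36.0,,28.8,200,293,"T = 293 K, 200 mM NaCl; lower Rg of Ahmed et al. in parentheses"
An16,185,50,5,,,46.3,43.2,43.2,,49.5,,,
Osteopontin,273,55,1.7,,,58.3,47.2,55.6,,60.5,,,
K19,99,35,1,,,32.0,29.6,30.1,,28.7,,288,Exp. T = 288 K
K18,130,38,3,,,37.6,34.8,35.8,,32.5,,288,Exp. T = 288 K
K17,143,36,2,,,39.8,37.4,38.9,,35.4,,288,Exp. T = 288 K
K10,167,40,1,,,43.6,39.0,39.9,,36.3,,288,Exp. T = 288 K
K27,171,37,2,,,44.2,40.6,42.0,,39.3,,288,Exp. T = 288 K
K16,174,39,3,,,44.7,41.8,43.8,,40.0,,288,Exp. T = 288 K
K25,185,41,2,,,46.3,39.7,39.1,,34.2,,288,Exp. T = 288 K
K32,202,41.5,3,,,48.8,44.7,46.4,,40.1,,288,Exp. T = 288 K
K23,254,49,2,,,55.7,47.3,47.6,,48.9,,288,"Exp. T = 288 K; scaling cell printed as 54.7 in the source compilation, corrected to 55.7 for consistency with the printed deviation table and the underlying power law"
K44,283,52,2,,,59.6,51.0,52.2,,50.8,,288,Exp. T = 288 K
hTau23,352,53,3,,,67.7,57.1,59.9,,52.3,,288,Exp. T = 288 K
hTau40,441,65,3,,,77.4,62.9,64.1,,40.8,140,288,"Exp. T = 288 K, 140 mM NaCl"
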