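name,n_residues,rg_exp,rg_exp_err,rg_exp_alt,rg_exp_alt_err,rg_scaling,rg_sop_idp,rg_bead_necklace,rg_bead_necklace_alt,rg_martini,salt_mM,temperature_K,comment
KEIF,35,17.6,,,,16.8,,16.0,,16.0,,,Atomistic reference 16.4
(Histatin 5)2,48,18.7,,,,,,21.0,,23.6,,,Atomistic reference 23.3
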