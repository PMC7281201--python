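component,mass_fraction_mg_per_mg,sd
protein,0.41,0.010
glycogen,0.417,0.036
carbohydrate,0.103,
lipid,0.0370,0.0005
rna,0.0441,0.0016
dna,0.0045,0.00023
chlorophyll_a,0.0049,0.0006
carotenoid,0.0035,0.0002
phycobiliprotein,0.00031,0.00004
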