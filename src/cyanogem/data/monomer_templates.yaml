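# Default monomer templates for macromolecular biomass components.
#
# Each component maps to a list of monomers with a mole fraction and the
# elemental formula of the *polymerized* residue (monomer minus the water
# released on condensation, where applicable).  Residue molar masses are
# computed from the formulas with standard atomic weights.  Profiles are
# normalized to sum to exactly 1 on load.
#
# Sources of the defaults:
#   protein          — average bacterial amino-acid usage (E. coli biomass
#                      composition); residues = amino acid - H2O
#   rna / dna        — equimolar NMP / dNMP residues (nucleoside
#                      monophosphate - H2O)
#   glycogen,
#   carbohydrate     — anhydroglucose (glucosyl) units, C6H10O5
#   lipid            — thylakoid/membrane lipid species with a
#                      C16:0/C18:1-dominated acyl profile (MGDG and PG)
#   chlorophyll_a    — intact chlorophyll a
#   carotenoid       — beta-carotene
#   phycobiliprotein — protein-like (alias)
#
# Soluble pool, inorganic ions and peptidoglycan have no default template
# here; supply profiles for them when they are present in the input CSV.

protein:
  - {id: ala, mole_fraction: 0.0957, formula: C3H5NO}
  - {id: arg, mole_fraction: 0.0551, formula: C6H12N4O}
  - {id: asn, mole_fraction: 0.0447, formula: C4H6N2O2}
  - {id: asp, mole_fraction: 0.0447, formula: C4H5NO3}
  - {id: cys, mole_fraction: 0.0170, formula: C3H5NOS}
  - {id: gln, mole_fraction: 0.0489, formula: C5H8N2O2}
  - {id: glu, mole_fraction: 0.0489, formula: C5H7NO3}
  - {id: gly, mole_fraction: 0.1145, formula: C2H3NO}
  - {id: his, mole_fraction: 0.0177, formula: C6H7N3O}
  - {id: ile, mole_fraction: 0.0543, formula: C6H11NO}
  - {id: leu, mole_fraction: 0.0839, formula: C6H11NO}
  - {id: lys, mole_fraction: 0.0641, formula: C6H12N2O}
  - {id: met, mole_fraction: 0.0286, formula: C5H9NOS}
  - {id: phe, mole_fraction: 0.0344, formula: C9H9NO}
  - {id: pro, mole_fraction: 0.0412, formula: C5H7NO}
  - {id: ser, mole_fraction: 0.0403, formula: C3H5NO2}
  - {id: thr, mole_fraction: 0.0474, formula: C4H7NO2}
  - {id: trp, mole_fraction: 0.0106, formula: C11H10N2O}
  - {id: tyr, mole_fraction: 0.0258, formula: C9H9NO2}
  - {id: val, mole_fraction: 0.0791, formula: C5H9NO}

glycogen:
  - {id: glucosyl_glycogen, mole_fraction: 1.0, formula: C6H10O5}

carbohydrate:
  - {id: glucosyl_carb, mole_fraction: 1.0, formula: C6H10O5}

lipid:
  - {id: mgdg_160_181, mole_fraction: 0.7, formula: C43H80O10}
  - {id: pg_160_181, mole_fraction: 0.3, formula: C40H77O10P}

rna:
  - {id: amp, mole_fraction: 0.25, formula: C10H12N5O6P}
  - {id: gmp, mole_fraction: 0.25, formula: C10H12N5O7P}
  - {id: cmp, mole_fraction: 0.25, formula: C9H12N3O7P}
  - {id: ump, mole_fraction: 0.25, formula: C9H11N2O8P}

dna:
  - {id: damp, mole_fraction: 0.25, formula: C10H12N5O5P}
  - {id: dgmp, mole_fraction: 0.25, formula: C10H12N5O6P}
  - {id: dcmp, mole_fraction: 0.25, formula: C9H12N3O6P}
  - {id: dtmp, mole_fraction: 0.25, formula: C10H13N2O7P}

chlorophyll_a:
  - {id: chla, mole_fraction: 1.0, formula: C55H72MgN4O5}

carotenoid:
  - {id: b_carotene, mole_fraction: 1.0, formula: C40H56}

phycobiliprotein: protein
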