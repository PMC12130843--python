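# Default charge-group definitions for ECC group-mode scaling.
#
# Maps residue names to the atom names of the charge group that carries the
# residue's integer formal charge (CHARMM-style atom naming).  These defaults
# are ILLUSTRATIVE: force-field ports differ in group membership and atom
# naming, so edit or replace this file to match your topology before scaling
# production systems.  Monatomic ions are single-atom groups.
group_mode:
  ASP: [CB, HB1, HB2, CG, OD1, OD2]          # -CH2-CO2(-), formal -1
  GLU: [CG, HG1, HG2, CD, OE1, OE2]          # -CH2-CO2(-), formal -1
  LYS: [CE, HE1, HE2, NZ, HZ1, HZ2, HZ3]     # -CH2-NH3(+), formal +1
  ARG: [CD, HD1, HD2, NE, HE, CZ, NH1, HH11, HH12, NH2, HH21, HH22]  # guanidinium, +1
  HSP: [CB, HB1, HB2, CG, ND1, HD1, CD2, HD2, NE2, HE2, CE1, HE1]    # protonated His, +1
  # charged termini (patched residues)
  NTER: [N, HT1, HT2, HT3, CA, HA]           # -NH3(+), formal +1
  CTER: [C, OT1, OT2]                        # -CO2(-), formal -1
  # monatomic ions (CHARMM and plain names)
  POT: [POT]
  K: [K]
  SOD: [SOD]
  NA: [NA]
  CLA: [CLA]
  CL: [CL]
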