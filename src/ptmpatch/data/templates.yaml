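# Executable modification templates.
#
# Each template turns a parent residue block into a product residue block:
#   deletions: atom names removed from the parent
#   renames:   [old, new] pairs applied after deletions
#   additions: [name, ref_bond, ref_angle, ref_dihedral, r_nm, theta_deg, phi_deg]
#              placed in order; later additions may reference earlier ones.
# Atom types/charges/masses of added atoms come from the product block.
# Geometry uses ideal values from standard chemical tables (the upstream
# tool's pre-minimized internal coordinates are not published).

phospho_ser:
  parent: SER
  product: SEP
  deletions: [HG]
  renames: []
  additions:
    - [P,   OG, CB, CA, 0.161, 109.5, 180.0]
    - [O1P, P,  OG, CB, 0.148, 109.5,  60.0]
    - [O2P, P,  OG, CB, 0.148, 109.5, 180.0]
    - [O3P, P,  OG, CB, 0.148, 109.5, -60.0]

phospho_thr:
  parent: THR
  product: TPO
  deletions: [HG1]
  renames: []
  additions:
    - [P,   OG1, CB,  CA, 0.161, 109.5, 180.0]
    - [O1P, P,   OG1, CB, 0.148, 109.5,  60.0]
    - [O2P, P,   OG1, CB, 0.148, 109.5, 180.0]
    - [O3P, P,   OG1, CB, 0.148, 109.5, -60.0]

phospho_tyr:
  parent: TYR
  product: PTR
  deletions: [HH]
  renames: []
  additions:
    - [P,   OH, CZ, CE1, 0.161, 109.5, 180.0]
    - [O1P, P,  OH, CZ,  0.148, 109.5,  60.0]
    - [O2P, P,  OH, CZ,  0.148, 109.5, 180.0]
    - [O3P, P,  OH, CZ,  0.148, 109.5, -60.0]

acetyl_lys:
  parent: LYS
  product: ALY
  deletions: [HZ1, HZ2, HZ3]
  renames: []
  additions:
    - [HZ,  NZ, CE, CD, 0.100, 120.0,   0.0]
    - [CH,  NZ, CE, CD, 0.133, 120.0, 180.0]
    - [OH,  CH, NZ, CE, 0.123, 120.0,   0.0]
    - [CH3, CH, NZ, CE, 0.153, 120.0, 180.0]

methyl_lys:
  parent: LYS
  product: MLZ
  deletions: [HZ3]
  renames: []
  additions:
    - [CM, NZ, CE, CD, 0.147, 109.5, -60.0]

methyl_lys2:  # chained: second methylation of an already-modified residue
  parent: MLZ
  product: MLY
  deletions: [HZ2]
  renames: [[CM, CM1]]
  additions:
    - [CM2, NZ, CE, CD, 0.147, 109.5, 180.0]

methyl_lys3:  # chained: third methylation
  parent: MLY
  product: M3L
  deletions: [HZ1]
  renames: []
  additions:
    - [CM3, NZ, CE, CD, 0.147, 109.5, 60.0]

dimethyl_lys:
  parent: LYS
  product: MLY
  deletions: [HZ2, HZ3]
  renames: []
  additions:
    - [CM1, NZ, CE, CD, 0.147, 109.5, 180.0]
    - [CM2, NZ, CE, CD, 0.147, 109.5, -60.0]

trimethyl_lys:
  parent: LYS
  product: M3L
  deletions: [HZ1, HZ2, HZ3]
  renames: []
  additions:
    - [CM1, NZ, CE, CD, 0.147, 109.5,  60.0]
    - [CM2, NZ, CE, CD, 0.147, 109.5, 180.0]
    - [CM3, NZ, CE, CD, 0.147, 109.5, -60.0]

methyl_arg:
  parent: ARG
  product: RME
  deletions: [HH11]
  renames: []
  additions:
    - [CQ, NH1, CZ, NE, 0.147, 120.0, 0.0]

hydroxy_pro:
  parent: PRO
  product: HYP
  deletions: []
  renames: []
  additions:
    - [OD1, CG,  CB, CA, 0.143, 109.5, 120.0]
    - [HD1, OD1, CG, CB, 0.100, 109.5, 180.0]

carboxy_glu:
  parent: GLU
  product: CGU
  deletions: []
  renames: [[CD, CD1], [OE1, OE11], [OE2, OE12]]
  additions:
    - [CD2,  CG,  CB, CA, 0.153, 109.5,  60.0]
    - [OE21, CD2, CG, CB, 0.125, 120.0,   0.0]
    - [OE22, CD2, CG, CB, 0.125, 120.0, 180.0]

nitro_tyr:
  parent: TYR
  product: NIY
  deletions: []
  renames: []
  additions:
    - [NN,  CE1, CD1, CG,  0.140, 120.0, 180.0]
    - [ON1, NN,  CE1, CD1, 0.123, 120.0,   0.0]
    - [ON2, NN,  CE1, CD1, 0.123, 120.0, 180.0]

carbonyl_lys:
  parent: LYS
  product: KAS
  deletions: [NZ, HZ1, HZ2, HZ3]
  renames: []
  additions:
    - [OZ, CE, CD, CG, 0.123, 120.0, 0.0]

carbonyl_arg:
  parent: ARG
  product: RGS
  deletions: [NE, HE, CZ, NH1, HH11, HH12, NH2, HH21, HH22]
  renames: []
  additions:
    - [OE, CD, CG, CB, 0.123, 120.0, 0.0]

carbonyl_pro:
  parent: PRO
  product: PGS
  deletions: []
  renames: []
  additions:
    - [H,  N,  CA, C,  0.100, 120.0, 180.0]
    - [OD, CD, CG, CB, 0.123, 120.0,   0.0]

carbonyl_thr:
  parent: THR
  product: TKB
  deletions: [HG1]
  renames: []
  additions: []

deamidate_asn:
  parent: ASN
  product: ASP
  deletions: [ND2, HD21, HD22]
  renames: []
  additions:
    - [OD2, CG, CB, CA, 0.125, 120.0, 180.0]

deamidate_gln:
  parent: GLN
  product: GLU
  deletions: [NE2, HE21, HE22]
  renames: []
  additions:
    - [OE2, CD, CG, CB, 0.125, 120.0, 180.0]

amidate_asp:  # registry-defined reverse of deamidate_asn
  parent: ASP
  product: ASN
  deletions: [OD2]
  renames: []
  additions:
    - [ND2,  CG,  CB, CA, 0.134, 120.0, 180.0]
    - [HD21, ND2, CG, CB, 0.100, 120.0,   0.0]
    - [HD22, ND2, CG, CB, 0.100, 120.0, 180.0]

amidate_glu:  # registry-defined reverse of deamidate_gln
  parent: GLU
  product: GLN
  deletions: [OE2]
  renames: []
  additions:
    - [NE2,  CD,  CG, CB, 0.134, 120.0, 180.0]
    - [HE21, NE2, CD, CG, 0.100, 120.0,   0.0]
    - [HE22, NE2, CD, CG, 0.100, 120.0, 180.0]

oxidize_met:
  parent: MET
  product: SME
  deletions: []
  renames: []
  additions:
    - [OE, SD, CG, CB, 0.150, 99.0, 60.0]

oxidize_cys:
  parent: CYS
  product: CSO
  deletions: [HG]
  renames: []
  additions:
    - [OD, SG, CB, CA, 0.165,  99.0, 180.0]
    - [HD, OD, SG, CB, 0.100, 109.5, 180.0]

nterm_acetyl_ala:
  parent: ALA
  product: AYA
  deletions: []
  renames: []
  additions:
    - [CP, N,  CA, C,  0.133, 120.0,   0.0]
    - [OP, CP, N,  CA, 0.123, 120.0,   0.0]
    - [CQ, CP, N,  CA, 0.153, 120.0, 180.0]
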