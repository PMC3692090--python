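# United-atom parameter table (single packaged set; both force-field
# flavours map onto it -- parameter fidelity is a documented non-goal,
# gradient correctness is the tested contract).
#
# Functional forms:
#   bond      V = 1/2 kb (b - b0)^2            kb in kJ/mol/nm^2
#   angle     V = 1/2 kt (theta - theta0)^2    kt in kJ/mol/rad^2
#   dihedral  V = k (1 + cos(n phi - phi_s))   k in kJ/mol
#   LJ 12-6 with Lorentz-Berthelot combination; plain truncation at the
#   cutoff (a pair contributes iff r < cutoff); Coulomb 1/(4 pi eps0) q q / r.
#
# Atom type classes drive equilibrium angles at the central atom:
#   tet -> 109.5 deg, tri -> 120.0 deg, bent -> 99.0 deg.

types:
  N:   {element: N, mass: 14.0067, cls: tri,  sigma: 0.30, epsilon: 0.090}   # amide nitrogen
  NL:  {element: N, mass: 14.0067, cls: tet,  sigma: 0.30, epsilon: 0.090}   # sp3 amine nitrogen
  NR:  {element: N, mass: 14.0067, cls: tri,  sigma: 0.30, epsilon: 0.090}   # aromatic ring nitrogen
  NT:  {element: N, mass: 14.0067, cls: tri,  sigma: 0.30, epsilon: 0.090}   # amide/guanidinium side-chain N
  NX:  {element: N, mass: 14.0067, cls: tri,  sigma: 0.30, epsilon: 0.090}   # nitro-group nitrogen
  C:   {element: C, mass: 12.011,  cls: tri,  sigma: 0.32, epsilon: 0.045}   # bare carbon (carbonyl, substituted aromatic)
  CR1: {element: C, mass: 13.019,  cls: tri,  sigma: 0.32, epsilon: 0.045}   # united aromatic CH
  CH1: {element: C, mass: 13.019,  cls: tet,  sigma: 0.34, epsilon: 0.018}   # united aliphatic CH
  CH2: {element: C, mass: 14.027,  cls: tet,  sigma: 0.34, epsilon: 0.024}   # united aliphatic CH2
  CH3: {element: C, mass: 15.035,  cls: tet,  sigma: 0.34, epsilon: 0.030}   # united aliphatic CH3
  O:   {element: O, mass: 15.9994, cls: tri,  sigma: 0.27, epsilon: 0.075}   # carbonyl/sulfoxide oxygen
  OA:  {element: O, mass: 15.9994, cls: tet,  sigma: 0.27, epsilon: 0.075}   # hydroxyl/ester oxygen
  OM:  {element: O, mass: 15.9994, cls: tri,  sigma: 0.27, epsilon: 0.090}   # charged oxygen (carboxylate, phosphate)
  H:   {element: H, mass: 1.008,   cls: none, sigma: 0.18, epsilon: 0.012}   # polar hydrogen (small LJ shell)
  S:   {element: S, mass: 32.06,   cls: bent, sigma: 0.33, epsilon: 0.120}
  P:   {element: P, mass: 30.9738, cls: tet,  sigma: 0.34, epsilon: 0.090}

constants:
  kb: 3000.0            # kJ/mol/nm^2 (soft set: keeps steepest descent well-conditioned)
  ktheta: 30.0          # kJ/mol/rad^2
  coulomb: 138.935458   # kJ mol^-1 nm e^-2
  charge_scale: 0.2     # screening factor applied to all block charges at load
  default_cutoff: 1.4   # nm

angle_theta0:  # degrees, by central-atom class
  tet: 109.5
  tri: 120.0
  bent: 99.0

# Ideal bond lengths (nm) keyed by unordered type pair.  The same table
# feeds the topology builder and the peptide fixture geometry, so freshly
# built fixtures start near their bonded-term equilibrium.
bond_lengths:
  - [N,   CH1, 0.147]
  - [N,   CH2, 0.147]
  - [N,   H,   0.100]
  - [N,   C,   0.133]
  - [CH1, C,   0.153]
  - [CH2, C,   0.153]
  - [C,   O,   0.123]
  - [CH1, CH1, 0.153]
  - [CH1, CH2, 0.153]
  - [CH1, CH3, 0.153]
  - [CH2, CH2, 0.153]
  - [CH2, CH3, 0.153]
  - [CH1, OA,  0.143]
  - [CH2, OA,  0.143]
  - [OA,  H,   0.100]
  - [CH2, S,   0.183]
  - [CH3, S,   0.183]
  - [S,   H,   0.133]
  - [C,   OM,  0.125]
  - [C,   NT,  0.134]
  - [NT,  H,   0.100]
  - [NT,  CH2, 0.147]
  - [NT,  CH3, 0.147]
  - [NL,  CH2, 0.147]
  - [NL,  CH3, 0.147]
  - [NL,  H,   0.100]
  - [C,   C,   0.139]
  - [C,   CR1, 0.139]
  - [CR1, CR1, 0.139]
  - [C,   OA,  0.136]
  - [C,   NR,  0.138]
  - [CR1, NR,  0.138]
  - [NR,  H,   0.100]
  - [C,   CH3, 0.153]
  - [OA,  P,   0.161]
  - [OM,  P,   0.148]
  - [S,   O,   0.150]
  - [S,   OA,  0.165]
  - [NX,  C,   0.140]
  - [NX,  CR1, 0.140]
  - [NX,  OM,  0.123]

# Dihedral rules by central-bond character.  A single proper dihedral is
# generated per eligible central bond (lowest-index outer neighbours).
dihedral_rules:
  conjugated: {n: 2, phi_s: 180.0, k: 5.0}    # both central atoms trigonal
  aliphatic:  {n: 3, phi_s: 0.0,   k: 1.5}    # both central atoms tetrahedral/bent
  mixed:      {n: 3, phi_s: 0.0,   k: 2.0}
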