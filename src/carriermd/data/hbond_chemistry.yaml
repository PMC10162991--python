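# Hydrogen-bond donor/acceptor chemistry and aromatic ring definitions
# for standard amino-acid residues (CHARMM/PDB v3 atom naming).
#
# donors: residue -> list of [heavy_atom, [attached polar hydrogens]]
# acceptors: residue -> list of heavy atoms (N/O lone-pair carriers)
# rings: residue -> list of aromatic rings, each a list of ring atoms.
#
# Backbone N-H (donor) and C=O (acceptor) apply to every amino acid and
# are added programmatically; this file lists sidechain chemistry only.

donors:
  ARG: [[NE, [HE]], [NH1, [HH11, HH12]], [NH2, [HH21, HH22]]]
  LYS: [[NZ, [HZ1, HZ2, HZ3]]]
  HIS: [[ND1, [HD1]], [NE2, [HE2]]]
  TRP: [[NE1, [HE1]]]
  ASN: [[ND2, [HD21, HD22]]]
  GLN: [[NE2, [HE21, HE22]]]
  SER: [[OG, [HG, HG1]]]
  THR: [[OG1, [HG1]]]
  TYR: [[OH, [HH]]]
  CYS: [[SG, [HG, HG1]]]

acceptors:
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]
  ASN: [OD1]
  GLN: [OE1]
  SER: [OG]
  THR: [OG1]
  TYR: [OH]
  HIS: [ND1, NE2]
  MET: [SD]

rings:
  PHE: [[CG, CD1, CD2, CE1, CE2, CZ]]
  TYR: [[CG, CD1, CD2, CE1, CE2, CZ]]
  HIS: [[CG, ND1, CD2, CE1, NE2]]
  TRP: [[CG, CD1, CD2, NE1, CE2], [CD2, CE2, CE3, CZ2, CZ3, CH2]]
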