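# Residue chemistry tables, version 1.
#
# Lone-pair counts: every oxygen acceptor carries 2, every unprotonated ring
# nitrogen carries 1. The exocyclic amine nitrogen (N6/N4/N2) donates its lone
# pair into the ring system and therefore never appears as an acceptor.
#
# Capacity counting convention (internal chain residue): the 5'-phosphate
# contributes both nonbridging oxygens (OP1/OP2) plus the bridging O5'; O4',
# O3' and (RNA) O2' complete the six backbone/sugar oxygens; no terminal
# hydroxyl protons are counted. Under this convention the four canonical
# ribonucleotides together hold 62 acceptor lone pairs and 12 polar H's.
version: 1
nucleotides:
  A:
    kind: rna
    letter: A
    base_atoms: [N9, C8, N7, C5, C6, N6, N1, C2, N3, C4]
    amine: {nitrogen: N6, hydrogens: [H61, H62], carbon: C6, refs: [N1, C5]}
    base_acceptors: {N1: 1, N3: 1, N7: 1}
    base_donors: {N6: 2}
  C:
    kind: rna
    letter: C
    base_atoms: [N1, C2, O2, N3, C4, N4, C5, C6]
    amine: {nitrogen: N4, hydrogens: [H41, H42], carbon: C4, refs: [N3, C5]}
    base_acceptors: {O2: 2, N3: 1}
    base_donors: {N4: 2}
  G:
    kind: rna
    letter: G
    base_atoms: [N9, C8, N7, C5, C6, O6, N1, C2, N2, N3, C4]
    amine: {nitrogen: N2, hydrogens: [H21, H22], carbon: C2, refs: [N1, N3]}
    base_acceptors: {O6: 2, N3: 1, N7: 1}
    base_donors: {N1: 1, N2: 2}
  U:
    kind: rna
    letter: U
    base_atoms: [N1, C2, O2, N3, C4, O4, C5, C6]
    amine: null
    base_acceptors: {O2: 2, O4: 2}
    base_donors: {N3: 1}
  DA:
    kind: dna
    letter: A
    base_atoms: [N9, C8, N7, C5, C6, N6, N1, C2, N3, C4]
    amine: null
    base_acceptors: {N1: 1, N3: 1, N7: 1}
    base_donors: {N6: 2}
  DC:
    kind: dna
    letter: C
    base_atoms: [N1, C2, O2, N3, C4, N4, C5, C6]
    amine: null
    base_acceptors: {O2: 2, N3: 1}
    base_donors: {N4: 2}
  DG:
    kind: dna
    letter: G
    base_atoms: [N9, C8, N7, C5, C6, O6, N1, C2, N2, N3, C4]
    amine: null
    base_acceptors: {O6: 2, N3: 1, N7: 1}
    base_donors: {N1: 1, N2: 2}
  DT:
    kind: dna
    letter: T
    base_atoms: [N1, C2, O2, N3, C4, O4, C5, C6, C7]
    amine: null
    base_acceptors: {O2: 2, O4: 2}
    base_donors: {N3: 1}
backbone:
  rna:
    acceptors: {OP1: 2, OP2: 2, "O5'": 2, "O4'": 2, "O3'": 2, "O2'": 2}
    donors: {"O2'": 1}
  dna:
    acceptors: {OP1: 2, OP2: 2, "O5'": 2, "O4'": 2, "O3'": 2}
    donors: {}
aa_backbone:
  acceptors: {O: 2}
  donors: {N: 1}
amino_acids:
  ALA: {side_acceptors: {}, side_donors: {}}
  ARG: {side_acceptors: {}, side_donors: {NE: 1, NH1: 2, NH2: 2}}
  ASN: {side_acceptors: {OD1: 2}, side_donors: {ND2: 2}}
  ASP: {side_acceptors: {OD1: 2, OD2: 2}, side_donors: {}}
  CYS: {side_acceptors: {}, side_donors: {}}
  GLN: {side_acceptors: {OE1: 2}, side_donors: {NE2: 2}}
  GLU: {side_acceptors: {OE1: 2, OE2: 2}, side_donors: {}}
  GLY: {side_acceptors: {}, side_donors: {}}
  HIS: {side_acceptors: {ND1: 1, NE2: 1}, side_donors: {NE2: 1}}
  ILE: {side_acceptors: {}, side_donors: {}}
  LEU: {side_acceptors: {}, side_donors: {}}
  LYS: {side_acceptors: {}, side_donors: {NZ: 3}}
  MET: {side_acceptors: {}, side_donors: {}}
  PHE: {side_acceptors: {}, side_donors: {}}
  PRO: {side_acceptors: {}, side_donors: {}}
  SER: {side_acceptors: {OG: 2}, side_donors: {OG: 1}}
  THR: {side_acceptors: {OG1: 2}, side_donors: {OG1: 1}}
  TRP: {side_acceptors: {}, side_donors: {NE1: 1}}
  TYR: {side_acceptors: {OH: 2}, side_donors: {OH: 1}}
  VAL: {side_acceptors: {}, side_donors: {}}
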