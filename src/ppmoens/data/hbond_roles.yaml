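# Hydrogen-bond donor/acceptor atom-name tables per residue kind.
#
# Donors are heavy atoms that carry at least one covalently bound hydrogen
# (the implementation verifies the bonded H geometrically).  The nucleotide
# entries cover the Watson-Crick and Hoogsteen faces of the four bases
# (amino N2/N4/N6, imino N1/N3); the amino-acid entries cover the backbone
# amide and the arginine guanidinium (NE, NH1, NH2).  Acceptors cover base
# ring nitrogens, exocyclic carbonyl oxygens, the phosphorodiamidate
# oxygens (O1P/O2P) and the backbone carbonyl.
#
# Edit freely: atom names are matched literally against the structure.
donors:
  nucleotide: [N1, N2, N3, N4, N6]
  amino_acid: [N, NE, NH1, NH2]
  linker: []
acceptors:
  nucleotide: [N1, N3, N7, O2, O4, O6, O1P, O2P]
  amino_acid: [O]
  linker: [O1, O2, O3]
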