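# Bundled species map: united-atom sterols and phosphatidylcholines.
#
# Sterol carbons follow steroid numbering. The reference frame of a sterol is
# anchored on C13 with the x-axis along C13->C18 (off-plane methyl) and the
# xz-plane containing C13->C10; C6->C11 defines the in-plane orientation
# vector. Masses are united-atom (aliphatic hydrogens merged into carbons).
species:
  CHOL:
    role: sterol
    frame_atoms: [C13, C18, C10]
    orientation_atoms: [C6, C11]
    ring_atoms: [C1, C2, C3, C4, C5, C6, C7, C8, C9, C10,
                 C11, C12, C13, C14, C17, C18, C19]
    headgroup_anchor: O3
    atom_masses:
      C1: 14.027
      C2: 14.027
      C3: 13.019
      C4: 14.027
      C5: 12.011
      C6: 13.019
      C7: 14.027
      C8: 13.019
      C9: 13.019
      C10: 12.011
      C11: 14.027
      C12: 14.027
      C13: 12.011
      C14: 13.019
      C15: 14.027
      C16: 14.027
      C17: 13.019
      C18: 15.035
      C19: 15.035
      O3: 17.007

  # "Flat" cholesterol: C18/C19 removed. C18 is required to define the
  # molecular frame and is reconstructed tetrahedrally at C13 from its three
  # ring neighbors; it is therefore declared under reconstructed_atoms rather
  # than appearing in the coordinate files.
  DCHL:
    role: sterol
    frame_atoms: [C13, C18, C10]
    orientation_atoms: [C6, C11]
    ring_atoms: [C1, C2, C3, C4, C5, C6, C7, C8, C9, C10,
                 C11, C12, C13, C14, C17]
    reconstructed_atoms:
      C18:
        center: C13
        neighbors: [C12, C14, C17]
        bond_length: 0.153
    headgroup_anchor: O3
    atom_masses:
      C1: 14.027
      C2: 14.027
      C3: 13.019
      C4: 14.027
      C5: 12.011
      C6: 13.019
      C7: 14.027
      C8: 13.019
      C9: 13.019
      C10: 12.011
      C11: 14.027
      C12: 14.027
      C13: 12.011
      C14: 13.019
      C15: 14.027
      C16: 14.027
      C17: 13.019
      O3: 17.007

  DSPC:
    role: phospholipid
    sn1_chain_atoms: [C1A, C2A, C3A, C4A, C5A, C6A, C7A, C8A, C9A, C10A,
                      C11A, C12A, C13A, C14A, C15A, C16A, C17A, C18A]
    sn2_chain_atoms: [C1B, C2B, C3B, C4B, C5B, C6B, C7B, C8B, C9B, C10B,
                      C11B, C12B, C13B, C14B, C15B, C16B, C17B, C18B]
    headgroup_anchor: P
    atom_masses:
      P: 30.974
      C1A: 14.027
      C2A: 14.027
      C3A: 14.027
      C4A: 14.027
      C5A: 14.027
      C6A: 14.027
      C7A: 14.027
      C8A: 14.027
      C9A: 14.027
      C10A: 14.027
      C11A: 14.027
      C12A: 14.027
      C13A: 14.027
      C14A: 14.027
      C15A: 14.027
      C16A: 14.027
      C17A: 14.027
      C18A: 15.035
      C1B: 14.027
      C2B: 14.027
      C3B: 14.027
      C4B: 14.027
      C5B: 14.027
      C6B: 14.027
      C7B: 14.027
      C8B: 14.027
      C9B: 14.027
      C10B: 14.027
      C11B: 14.027
      C12B: 14.027
      C13B: 14.027
      C14B: 14.027
      C15B: 14.027
      C16B: 14.027
      C17B: 14.027
      C18B: 15.035

  # Di-oleoyl PC: same chain length, cis double bond at C9-C10 (CH sites).
  DOPC:
    role: phospholipid
    sn1_chain_atoms: [C1A, C2A, C3A, C4A, C5A, C6A, C7A, C8A, C9A, C10A,
                      C11A, C12A, C13A, C14A, C15A, C16A, C17A, C18A]
    sn2_chain_atoms: [C1B, C2B, C3B, C4B, C5B, C6B, C7B, C8B, C9B, C10B,
                      C11B, C12B, C13B, C14B, C15B, C16B, C17B, C18B]
    headgroup_anchor: P
    atom_masses:
      P: 30.974
      C1A: 14.027
      C2A: 14.027
      C3A: 14.027
      C4A: 14.027
      C5A: 14.027
      C6A: 14.027
      C7A: 14.027
      C8A: 14.027
      C9A: 13.019
      C10A: 13.019
      C11A: 14.027
      C12A: 14.027
      C13A: 14.027
      C14A: 14.027
      C15A: 14.027
      C16A: 14.027
      C17A: 14.027
      C18A: 15.035
      C1B: 14.027
      C2B: 14.027
      C3B: 14.027
      C4B: 14.027
      C5B: 14.027
      C6B: 14.027
      C7B: 14.027
      C8B: 14.027
      C9B: 13.019
      C10B: 13.019
      C11B: 14.027
      C12B: 14.027
      C13B: 14.027
      C14B: 14.027
      C15B: 14.027
      C16B: 14.027
      C17B: 14.027
      C18B: 15.035
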