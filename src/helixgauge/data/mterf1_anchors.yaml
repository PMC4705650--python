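# Default anchor residues for MTERF1 (chain A of the deposited specific
# complex, author numbering).  One Calpha per repeat motif plus the
# C-segment.  The two documented exceptions are A279 (motif 6, replacing the
# GPG-loop proline) and W383 (C-segment, which has no proline).  The seven
# S-loop proline residue numbers below are EXAMPLE DEFAULTS, not ground
# truth: they must be verified once against the deposited entry before being
# used on real coordinates, and can be overridden by any user YAML of the
# same shape.
anchors:
  - {chain: A, residue: 112, atom: CA}   # motif 1 S-loop proline (example)
  - {chain: A, residue: 145, atom: CA}   # motif 2 S-loop proline (example)
  - {chain: A, residue: 178, atom: CA}   # motif 3 S-loop proline (example)
  - {chain: A, residue: 211, atom: CA}   # motif 4 S-loop proline (example)
  - {chain: A, residue: 244, atom: CA}   # motif 5 S-loop proline (example)
  - {chain: A, residue: 279, atom: CA}   # motif 6: A279 (documented exception)
  - {chain: A, residue: 310, atom: CA}   # motif 7 S-loop proline (example)
  - {chain: A, residue: 343, atom: CA}   # motif 8 S-loop proline (example)
  - {chain: A, residue: 383, atom: CA}   # C-segment: W383 (documented exception)
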