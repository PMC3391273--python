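# Domain map for DgAS (PDB 3UCQ after removal of the expression tag and
# completion of the C-terminal tail; residues 1-650).
# RECONSTRUCTED, NOT FROM A PUBLISHED TABLE: interval boundaries are
# approximate, chosen so that the composite domain lengths match the
# reported architecture (N=84, A=331 as A1+A2+A3, B=81, B'=69, C=85).
N: 1-84
A1: 85-178
B: 179-259
A2: 260-395
B': 396-464
A3: 465-565
C: 566-650
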