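# Domain map for NpAS (PDB 1G5A, chain A, residues 1-628).
# RECONSTRUCTED, NOT FROM A PUBLISHED TABLE: interval boundaries are
# approximate, chosen so that the composite domain lengths match the
# reported architecture (N=89, A=323 as A1+A2+A3, B=76, B'=65, C=75).
N: 1-89
A1: 90-184
B: 185-260
A2: 261-395
B': 396-460
A3: 461-553
C: 554-628
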