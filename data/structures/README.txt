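Place input crystal structures here, e.g.:

  1G5A.pdb  -- Neisseria polysaccharea amylosucrase (628 residues, chain A)
  3UCQ.pdb  -- Deinococcus geothermalis amylosucrase (strip the N-terminal
               expression tag, residues -4..0, before analysis)

These files are not distributed with the package.
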