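# Default site-label assignments for the synthetic diketopiperazine
# substrates 1-3 (residue names DK1/DK2/DK3): atom name -> field site label.
# Deposited coordinate files use their own atom names; supply a custom map.
DK1:
  CD3: C-7
  CG1: C-2'
  CG3: C-5a
  CG2: C-6
DK2:
  CG1: C-2'
  CD1: C-3'
  CB2: C-5
DK3:
  CD1: C-3'
  CB2: C-5
  CG2: C-6
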