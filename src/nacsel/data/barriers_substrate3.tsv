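# Hydrogen-abstraction activation free energies (kcal/mol) for substrate 3
# in the truncated Fe(IV)-oxo theozyme model (text-quoted values only).
# site	delta_G_kcal_per_mol
C-5	5.3
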