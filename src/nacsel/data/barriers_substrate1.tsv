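# Hydrogen-abstraction activation free energies (kcal/mol) for substrate 1
# in the truncated Fe(IV)-oxo theozyme model. Only the value quoted in
# running text is shipped; the remaining per-site barriers appear solely in
# a figure table and must be transcribed by the user if needed.
# site	delta_G_kcal_per_mol
C-2'	6.4
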