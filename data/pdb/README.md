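# Crystal-structure inputs

Place the study's four PDB entries here as uncompressed text files to enable
the crystal-anchored tests and acceptance targets:

    1AO7.pdb   (index peptide, chain C = LLFGYPVYV)
    1QSE.pdb   (V7R variant)
    1QSF.pdb   (Y8A variant)
    1QRN.pdb   (P6A variant)

e.g. `curl -O https://files.rcsb.org/download/1AO7.pdb` for each entry.
The files are not redistributed with this repository.
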