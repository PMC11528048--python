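"""Reference peptide and synthetic domain sequences used in examples and
tests.

``KKED_X9_PEPTIDE`` is the published 28-residue [KKE/D]x9 peptide (nine
lysine doublets spaced by single E/D residues) used for in vitro
coacervation work on snoRNP lysine-rich domains.

``SYNTHETIC_CBF5_LIKE_IDR`` is a SYNTHETIC stand-in, not a native protein
sequence: a hand-constructed 92-residue domain reproducing the architecture
of the C-terminal KKE/D intrinsically disordered region of the yeast H/ACA
pseudouridine synthase Cbf5 (a short uncharged linker, a lysine-enriched
stretch with alternating positive and negative charge blocks, then a block
of KK doublets spaced by E/D/H/S). It is used where a domain of that class
is needed and the native sequence is not bundled. Its descriptors fall in
the class-typical ranges: FCR ~0.73, NCPR ~+0.12, kappa ~0.28 (strong
polyampholyte with moderate charge segregation).
"""

#: [KKE/D]x9: nine KK doublets spaced by single glutamate/aspartate residues.
KKED_X9_PEPTIDE = "KKEKKEKKDKKDKKEKKEKKDKKDKKEK"

#: synthetic Cbf5-like C-terminal IDR (92 aa); see module docstring.
SYNTHETIC_CBF5_LIKE_IDR = (
    "SGVNVDATEAP"  # uncharged linker off the folded domain
    "KKAKKKSTDEEDDDESKKVKKKAGEEDEDKK"  # lysine-enriched, alternating charge blocks
    "KKEKKDSKKEKKDKKESKKEKKDHKKEKKDKKSEEDDESKKAKKVKKTSK"  # KK-doublet block
)
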