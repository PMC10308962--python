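"""Carbon oxidation state (Z_C) of amino acids and proteins.

Z_C = (-h + 3n + 2o + 2s)/c summarizes how oxidized the carbon in a
molecule is; for proteins it is the carbon-weighted mean over residues.
"""

from redoxzc import AminoAcidTally, ElementalFormula, zc_from_formula, zc_from_tally

for name, formula in [
    ("glycine  C2H5NO2 ", ElementalFormula(2, 5, 1, 2, 0)),
    ("alanine  C3H7NO2 ", ElementalFormula(3, 7, 1, 2, 0)),
    ("cysteine C3H7NO2S", ElementalFormula(3, 7, 1, 2, 1)),
    ("leucine  C6H13NO2", ElementalFormula(6, 13, 1, 2, 0)),
]:
    print(f"Z_C({name}) = {zc_from_formula(formula):+.4f}")

# a short peptide: both computation routes give the same number
peptide = AminoAcidTally.from_sequence("GASTACKLM")
print(f"\nZ_C of peptide GASTACKLM = {zc_from_tally(peptide):+.4f}")
print("(carbon-weighted mean over residues; equals the whole-molecule")
print(" formula route because peptide-bond water carries no carbon)")
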