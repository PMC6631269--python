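"""Standardize raw SMILES and assign the dominant microspecies at pH 7.4.

Salt stripping, normalization and neutralization produce one canonical
neutral form per input; the rule-based ionizer then protonates/deprotonates
every recognized group whose pKa crosses physiological pH.
"""

from targetfish import RawStructure, ionize_at_ph, neutralize, standardize

raws = [
    RawStructure("aspirin_salt", "[Na+].CC(=O)Oc1ccccc1C(=O)[O-]"),
    RawStructure("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    RawStructure("glycine", "NCC(=O)O"),
    RawStructure("benzene", "c1ccccc1"),
]

for raw in raws:
    std = standardize(raw)
    ion = ionize_at_ph(std, ph=7.4)
    fired = ",".join(k for k, v in std.flags.items() if v) or "-"
    print(f"{raw.source_id:14s} {std.neutral_smiles:32s} -> {ion.ionized_smiles:32s}"
          f" charge={ion.net_formal_charge:+d}  flags={fired}")
    assert neutralize(ion.ionized_smiles) == std.neutral_smiles  # round trip

print("\nEach line: curated neutral form, its pH-7.4 dominant species and the")
print("net formal charge; acids lose protons (carboxylates), amines gain one,")
print("and glycine comes out as the zwitterion. Neutralization inverts it.")
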