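"""Theoretical a/b/y fragment ions with neutral losses.

Generates the fragment table for the glycated marker peptide. Fragments
covering residue K7 carry the +324.1056 Da glycation shift; smaller y/b
ions that exclude it do not — exactly the pattern used to localise the
modification in the middle of the peptide.
"""
from msemarker.chem import generate_fragments
from msemarker.chem.digest import PeptideRecord
from msemarker.chem.modifications import LACTULOSYLLYSINE

glycated = PeptideRecord("VLPVPQKAVPYPQR", "beta_casein", 185, 198, 1,
                         modifications=(LACTULOSYLLYSINE.site(7),))
fragments = generate_fragments(glycated, max_fragment_charge=2)
print(f"{len(fragments)} fragment ions (a/b/y, charges 1-2, with losses)")
for label in ["y3 +", "y7 +", "b10 ++", "y10 ++", "y12-C1H2N2 ++"]:
    ion = next(f for f in fragments if f.label == label)
    tag = "modified" if ion.modified else "unmodified"
    print(f"  [{label:14s}] m/z {ion.mz:9.4f}  ({tag})")
# y3 (PQR) excludes K7 and stays unmodified; b10/y10/y12 include K7 and
# shift by +324.1056/z. These m/z match the published fragment table.
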