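"""In-silico tryptic digestion and modification expansion.

Digests the bundled beta-casein sequence with up to two missed cleavages
and expands the glycation-bearing marker peptide over the modification
registry. Heating milk glycates lysine side chains (lactulosyllysine,
+324.1056 Da), which removes the tryptic cleavage site at that lysine.
"""
from pathlib import Path

from msemarker.chem import digest, expand_modifications, read_fasta
from msemarker.chem.modifications import LACTULOSYLLYSINE

FASTA = Path(__file__).parent.parent / "src" / "msemarker" / "data" / "milk_proteins_synthetic.fasta"

records = dict(read_fasta(FASTA))
peptides = digest(records["beta_casein"], missed_cleavages=2, protein_id="beta_casein")
print(f"beta-casein digest: {len(peptides)} peptides (MC <= 2)")

(marker,) = [p for p in peptides if p.sequence == "VLPVPQKAVPYPQR"]
print(f"marker peptide {marker.sequence}: position {marker.start}-{marker.end}, "
      f"MC {marker.missed_cleavages}, neutral mass {marker.neutral_mono_mass:.4f} Da")

for variant in expand_modifications(marker, [LACTULOSYLLYSINE]):
    print(f"  {variant.modification_names():24s} {variant.neutral_mono_mass:.4f} Da")
# The glycated variant is +324.1056 Da: the lactose Amadori adduct on K7,
# the internal missed-cleavage lysine where trypsin can no longer cut.
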