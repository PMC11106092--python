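"""Two-stage identification of selected features.

Matches five features (m/z + charge) against the digest database built
from the bundled milk proteins at 0.001% relative tolerance and prints the
per-feature report: peptide, protein, modification or fragment assignment,
or an explicit no-match statement.
"""
from pathlib import Path

from msemarker.features.detect import Feature
from msemarker.identify import (build_search_space, compile_report,
                                format_report_text, match_feature)

FASTA = Path(__file__).parent.parent / "src" / "msemarker" / "data" / "milk_proteins_synthetic.fasta"
space = build_search_space([FASTA])
print(f"search space: {len(space)} candidate species (precursors + fragments)")

features = [
    Feature(mz=458.7419, rt=323.9, charge=2, intensity=0, feature_id="FT66837"),
    Feature(mz=639.3498, rt=392.3, charge=3, intensity=0, feature_id="FT43359"),
    Feature(mz=880.4750, rt=461.6, charge=2, intensity=0, feature_id="FT48247"),
    Feature(mz=638.0087, rt=437.2, charge=3, intensity=0, feature_id="FT59844"),
    Feature(mz=425.2607, rt=369.1, charge=1, intensity=0, feature_id="FT11758"),
]
candidates = {f.feature_id: match_feature(f, space) for f in features}
report = compile_report(features, candidates)
print(format_report_text(report))
# FT43359 resolves to the glycated beta-casein peptide, FT48247 to an
# alpha-S1-casein peptide and FT11758 to a y3 fragment of ALPMHIR; ppm
# columns give the relative mass error of each assignment.
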