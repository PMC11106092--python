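# msemarker

Selection and identification of marker peptides from LC-MS^E bottom-up
proteomics data.

## The problem

Processed foods change their proteome in ways that are diagnostic of the
processing itself: heating milk, for instance, glycates lysine side chains
(the Amadori product lactulosyllysine, +C₁₂H₂₀O₁₀ = +324.1056 Da) and
abolishes the tryptic cleavage site at the modified lysine. Finding
*marker peptides* for such treatment from data-independent MS^E
acquisitions — where every cycle records a low-collision-energy scan
(intact precursors with their isotope envelopes) and a high-energy scan
(fragments of everything co-eluting) — requires three steps that this
package implements end to end, for any protein FASTA and any binary
sample contrast:

1. **Feature engineering** — mzML runs are reduced to a pair of linked
   tables: a samples × features intensity matrix (missing observations
   are NaN) and per-feature metadata (m/z, retention time in seconds,
   charge estimated from the 1.003355/z isotope spacing). Features
   agreeing in charge within |Δm/z| ≤ 0.01 and |Δrt| ≤ 5 s are merged
   across samples.
2. **Chemometrics** — PLS-DA (two latent components, NIPALS) on the class
   contrast, with features ranked by the variable importance in
   projection,

   VIP_j = √( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),  SSY_a = q_a²(t_aᵀt_a),

   normalised so mean(VIP²) = 1; the top-k (default 5) features become
   marker candidates.
3. **Identification** — each candidate's m/z is matched at 0.001%
   relative tolerance against an indexed search space holding every
   tryptic peptide (≤ 2 missed cleavages; cleavage C-terminal of K/R, not
   before P) of the supplied proteins, every single-modification variant
   (glycation, oxidation, methylation, acetylation as mass shifts) and
   every a/b/y fragment ion with neutral losses (−H₂O, −NH₃, −CH₂N₂).
   Matches are then verified in the raw spectra: the fine
   (isotopologue-resolved) isotope pattern, truncated at 99.95%
   cumulative abundance, against the nearest low-energy scan, and the
   fragment ladder against the nearest high/low-energy scans. No
   composite score is computed — the report exposes ppm errors, evidence
   counts and plausibility flags for individual interpretation.

A synthetic MS^E study generator with ground truth (planted marker
peptides with class fold-changes, noise analytes, instrument-like m/z,
retention-time and intensity noise) supports validation of every stage;
the package's audience is analytical chemists and proteomics
bioinformaticians who want the whole chain inspectable in Python rather
than locked inside vendor software.

## Worked example

Fragment ions of the glycated β-casein peptide VLPVPQKAVPYPQR
(`examples/02_fragment_ions.py`):

```
162 fragment ions (a/b/y, charges 1-2, with losses)
  [y3 +          ] m/z  400.2303  (unmodified)
  [y7 +          ] m/z  830.4519  (unmodified)
  [b10 ++        ] m/z  677.3792  (modified)
  [y10 ++        ] m/z  754.3856  (modified)
  [y12-C1H2N2 ++ ] m/z  831.4353  (modified)
```

y3 (PQR) excludes the glycated K7 and is unshifted; b10/y10/y12 include
it and carry +324.1056/z. Matching five observed features (m/z, charge)
against the digest of the seven bundled milk proteins
(`examples/06_identify_features.py`) assigns:

```
FT43359  m/z 639.3498  charge 3+
  VLPVPQKAVPYPQR (beta_casein)  modification Lactulosyllysine@K7  -1.39 ppm
FT48247  m/z 880.4750  charge 2+
  HQGLPQEVLNENLLR (as1_casein)  -1.27 ppm
FT11758  m/z 425.2607  charge 1+
  ALPMHIR (beta_LG)  fragment y3 +  -2.89 ppm
FT59844  m/z 638.0087  charge 3+
  No match found in the limitations of the search parameters
```

i.e. a heat-induced glycation marker, an unmodified casein peptide and an
in-source y3 fragment, each within a few ppm of theory.

The same chain runs from the shell:

```bash
msemarker run --seed 7 --out demo/          # simulate → features → select → identify
msemarker simulate --seed 1 --out study/    # or stage by stage
msemarker features --sheet study/sample_sheet.tsv --out ft/
```

Every intermediate artifact is TSV. The bundled FASTA
(`src/msemarker/data/milk_proteins_synthetic.fasta`) contains
reconstructed canonical milk-protein sequences for offline use; point
`--fasta` at your own UniProt download for real work.

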