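# Methods

This note documents the models, numerical choices and limitations behind
`msemarker`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Peptide chemistry

**Mass table.** A fixed internal snapshot of IUPAC 2013 isotope masses and
representative abundances for H, C, N, O, S ships with the code
(`chem/elements.py`). Fixing the table makes every computed m/z
reproducible; abundances of published fine-pattern tables computed with
other snapshots are only expected to agree to ~0.1 percentage points.
The proton mass (1.007276 Da) is the default charge carrier everywhere.
A `hydrogen` adduct option (neutral-atom mass, 1.007825 Da) exists
because some isotope-pattern tables print [M+zH]/z with the neutral-atom
convention; fragment arithmetic is proton-based. Both are exposed on
`ion_mz` and `fine_isotope_pattern`.

**Digestion.** Trypsin cleaves C-terminal of K/R except before P.
`digest` emits every peptide with 0..MC missed cleavages (default
MC = 2), annotated with its 1-based span and missed-cleavage count; a
brute-force substring oracle in the tests checks completeness and
labelling on random sequences.

**Modifications** are elemental deltas with site rules, applied at most
one per peptide by default (`max_mods=1`) — modified species are treated
as single mass shifts; combinations are opt-in. Defaults: lactulosyllysine
+C12H20O10 on K, oxidation +O on M, methylation +CH2 on K/R, acetylation
+C2H2O on K or the peptide N-terminus. The site sets for oxidation,
methylation and acetylation are deliberate choices, configurable in the
registry — restricting oxidation to methionine is the common default in
search engines. Because glycation abolishes the tryptic site,
a cleavage-blocking modification is only placed on a lysine trypsin left
uncut: an internal (missed-cleavage) position, a K before P, or the
protein's C-terminal residue. Cysteine carbamidomethylation is *not*
auto-applied; add it to the registry if your sample preparation alkylates.

**Fragments.** b/a ions from the N-terminus (a = b − CO), y ions from the
C-terminus (y = residues + H2O); m/z adds one proton per charge. Neutral
losses are applied once per fragment when a qualifying residue is present:
−H2O (S/T/E/D), −NH3 (K/R/Q/N), −CH2N2 (R). This minimal loss table
reproduces the published loss-annotated fragments of the worked example;
it is configurable per call. Modification deltas are included iff the
modified residue lies inside the fragment. Default fragment charges 1–2.
One published fragment row ("b13-H3N1 ++" at 651.3663) cannot be
reconciled with b/a/y ± loss arithmetic under any loss in this table
(checked numerically, modified and unmodified); it is not reproduced.

**Fine isotope patterns.** Per-element multinomial isotope distributions
are convolved across elements at full isotopologue resolution — species
sharing a nominal shift (e.g. ¹³C₂ vs ¹⁸O₁, 8 mDa apart at 3+) stay
distinct. Species are pruned by descending abundance until the requested
cumulative coverage (default 0.9995, i.e. a 0.05% cut-off) is reached;
`coverage=1.0` with `prune=0` is exhaustive and is tested against a
per-atom enumeration oracle at 1e-9 relative. The intermediate pruning
floor (1e-10 absolute) bounds the combinatorial blow-up for peptide-sized
formulas.

## Feature engineering

The detector is a deliberately simple, fully specified finder, not a
re-implementation of any external tool (substitute your own finder by
supplying a pre-computed feature table; the merge/selection stages only
need the TSV contract). Steps: (1) link centroided peaks across
consecutive scans into mass traces (tolerance 0.01 Da, ≥ 3 scans, ≤ 1
scan gap); (2) group co-eluting traces (apexes within 3 s) into isotope
envelopes by testing charges 1..3 with the 1.003355/z spacing, choosing
the charge explaining the most isotope positions; (3) report the
monoisotopic trace's intensity-weighted m/z, the apex retention time and
the summed envelope intensity. The envelope-position window (0.02 Da) is
wider than the trace tolerance because isotopologue fine structure (e.g.
³⁴S vs ¹³C₂) spreads a cluster by up to ~10 mDa per position; without
this, sulfur-containing analytes shed satellite features. Ungrouped
traces become charge-1 features flagged `ungrouped`.

Centroiding picks local maxima over contiguous above-threshold raster
segments, splitting at interior valleys; centroid m/z is the
intensity-weighted mean, centroid intensity the apex.

Merging is single-linkage over features agreeing in charge within
|Δm/z| ≤ 0.01 and |Δrt| ≤ 5 s, with deterministic (rt, m/z) ordering of
clusters and ids; representatives are intensity-weighted means.
Single-linkage is the simplest reproducible choice; its usual caveat
(chaining) is accepted and the tests check idempotence and order
independence rather than cluster-diameter bounds. Missing cells are NaN
in all files and reports; they become 0 only inside the chemometrics
preprocessing, where "no data" means "no observed intensity". Retention
times are seconds everywhere.

## Chemometrics

PLS-DA is fitted natively (NIPALS, PLS1, tolerance 1e-10, ≤ 500
iterations, deterministic) with y ∈ {0,1}; two components by default.
Columns are mean-centred and scaled to unit variance (sample std,
ddof = 1) — preprocessing is a package choice matching the default of
common PLS implementations, against which the fit is cross-checked to
1e-6 (up to sign) in the tests. Zero-variance columns are dropped with a
warning and are *absent* from VIP output rather than zero. VIP follows
the standard formula with SSY_a = q_a²(t_aᵀt_a); Σ VIP² = p holds to
machine precision and is asserted. Selection takes the top-k (default 5)
by VIP with ties broken by feature id; no automatic VIP > 1 threshold is
applied, since top-k selection is the interface. A class-presence filter
reports features observed in only one class (possibly an empty report —
itself a result).

## Identification

The search space indexes, by theoretical m/z: every digest peptide ×
modification variant as precursors at charges 1–3, plus a/b/y fragment
ions. Fragment ions enter the *matching* index singly charged by default:
multiply charged fragments belong to the verification stage, and indexing
them floods 2+ features with coincidental fragment hits (configurable via
`fragment_charges`). Matching requires the species charge to equal the
feature's detected charge and |Δm/z|/m/z ≤ 1e-5 (0.001%); candidates are
ordered by |ppm|, then fewer modifications, then shorter sequence — a
deterministic presentation order, not a score.

Isotope verification computes the candidate's fine pattern at its charge
(other charges optional) and pairs theoretical species with observed
peaks of the nearest low-energy scan within ±5 s *one-to-one*, closest
pairs first — an isotopologue whose nearest peak is already explained
stays unassigned, which is what makes the unassigned-species list
meaningful. Verdict `isotopes_found` needs ≥ 2 assigned species beyond
the monoisotopic one. Fragment verification searches all fragments of the
candidate *and* of its unmodified counterpart (both columns of the
published comparison style) in the nearest high- and low-energy scans;
an unmodified fragment whose span covers the modified residue is kept but
flagged `implausible_unmodified_fragment` — chemically it should carry
the modification, and the flag leaves the judgement to the analyst.
Features already explained as fragments skip fragment verification.
The report exposes evidence counts, ppm errors and flags; deliberately no
composite score.

The rt window (±5 s) reuses the merge tolerance; the spectrum-selection
rule is nearest-scan-in-window.

## Synthetic MS^E studies

The generator emulates the targeted study design: two classes
(8 + 8 replicates), alternating low/high-energy scans (2 s cycle),
planted marker peptides whose low-energy envelopes come from the fine
isotope engine and whose high-energy fragments come from the fragment
engine (per-fragment yields uniform in [0.05, 0.3], seeded), plus noise
analytes with synthetic 2–4-peak envelopes. Noise models: log-normal
intensity (σ = 0.3), Gaussian m/z error (3 ppm), Gaussian rt jitter
(1 s), Gaussian chromatographic peak (FWHM 10 s — no peak model is
prescribed by the study design, so a symmetric Gaussian is the neutral
choice). Everything derives from the seed; identical seeds give
byte-identical mzML. The ground truth records theoretical *and* realised
(per-sample) m/z and rt, since a 3 ppm shift at m/z 1300 (≈ 4 mDa) is
larger than the detector's own accuracy.

Not emulated: peak tailing, chimeric interference beyond peak summation,
detector saturation, baseline/electronic noise, ion mobility. Passing the
recovery tests therefore demonstrates the pipeline's correctness under
idealised instrument behaviour, not its robustness to real
chromatography.

**Problem sizes.** The reference recovery study (5 markers at 4-fold
change among 500 noise analytes, 8 + 8 samples, 20 seeds) runs the full
in-memory pipeline per seed; mzML round-tripping is exercised by its own
tests rather than inside the seed loop. The package-default study
conditions are exactly these.

## Bundled reference sequences

`data/milk_proteins_synthetic.fasta` holds reconstructed canonical
precursor sequences of the seven milk proteins (αS1-, αS2-, β-, κ-casein,
α-lactalbumin, β-lactoglobulin, BSA), bundled so identification examples
and tests run offline; it is a synthetic stand-in, and the marker-peptide
regions used in assertions are checksum-verified against published m/z
values. Use a current UniProt download for real analyses.

## Known limitations

- The worked-example feature at m/z 458.7419 (2+) lies 3.4 ppm from the
  canonical β-lactoglobulin peptide IDALNENK, inside the stated 0.001%
  tolerance, so this implementation reports a candidate where the
  reference outcome is a no-match; reproducing that outcome would need a
  ~3 ppm tolerance. The stated tolerance is kept and the discrepancy is
  asserted visibly in the acceptance suite.
- Single-linkage merging can chain drifting features across samples.
- The finder assigns charge by isotope-position counting; co-eluting
  analytes closer than the envelope window can merge.
- I/L are taken literally (no mass-equivalence collapsing); matching is
  by mass, so I/L variants tie at identical ppm and surface as ties.
- No FDR/decoy machinery and no de novo sequencing — identification is
  database-limited by design.
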