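# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Mass chemistry

Residue masses are the standard IUPAC monoisotopic and average values
(water 18.01056 / 18.0153 Da). Ion *m/z* uses the proton mass 1.00728 Da —
not the hydrogen atomic weight 1.00794 — which is what reproduces the
published 2-decimal precursor values. Carbamidomethylation is a fixed
modification of +57.02146 Da (mono) / +57.0513 Da (avg) per cysteine,
reflecting iodoacetamide alkylation after disulfide reduction in the
sequencing workflow. Two mass conventions coexist deliberately and are
always explicit parameters: peptide precursor values are **monoisotopic**
masses of CAM-modified peptides, while intact-chain values are **average**
masses of the reduced linear chain with unmodified cysteines (each
disulfide, if requested, subtracts 2 × 1.008 Da). Internal values are kept
at full float precision; rounding (half-even, 2 decimals) happens only at
the presentation layer.

Trypsin cleaves C-terminal to K/R except before P. Coordinates are 1-based
inclusive throughout. The default missed-cleavage cap is 2; note that the
C-terminal ATPI-II peptide (…ATCHPRE) retains three internal K/R sites, so
verification of that chain uses a cap of 3.

### Published-data erratum

Eleven of the twelve published "calculated" precursor rows reproduce
exactly at 2 decimals under the conventions above, as do both intact
average masses (6719.43 / 6604.39 Da). The remaining row — the +4
precursor of CRGYFPRYYYNTEAGK, printed as 509.97 calculated / 510.32
observed — is irreproducible: the correct CAM monoisotopic value is
511.99, and an exhaustive scan of every digest product of the
mass-verified chain at charges 1–6 finds nothing within 1.6 *m/z* of the
printed observed value either. Both entries of that row are treated as a
printing erratum: the row is retained as input (flagged `erratum`) but
excluded from exact reproduction checks, and the residue span it alone
covers (15–21) is consequently not claimable from precursor evidence at
the 0.5 Th tolerance. One acceptance-level test states the full-strength
claim (7/7 matched, coverage 1.0) and is expected to fail on the published
values; the attainable outcome (6/7, coverage 53/60) is pinned separately.

## MS/MS identification

Fragment theory: b_i is the protonated N-terminal fragment of i residues,
y_i the protonated C-terminal fragment plus water; a = b − 27.99491 (CO),
and z is the z-dot convention, y − 16.01872 (NH₃ loss with retention of
the radical hydrogen). a/z ions are annotation-only and never drive tag
deduction. The b/y complementarity identity b_i + y_{n−i} = M + 2·1.00728
(singly charged) is enforced as a test property.

Annotation assigns theoretical ions to peaks greedily by increasing
|Δm/z| within tolerance, each peak and ion used at most once; it is tested
for exact agreement with an exhaustive all-pairs oracle.

Tag deduction replaces the manual read-off of ladder spacings: a directed
acyclic gap graph over the sorted peak list has an edge wherever a peak
spacing matches a residue mass (including fixed-mod shifts) within
tolerance, and every maximal path of at least the minimum length becomes a
tag of residue ambiguity classes. I/L are always merged; K/Q merge only
when the tolerance covers their 0.03638 Da gap. Path enumeration is capped
(default 200/spectrum) to bound combinatorics on noisy spectra. Defaults
are 0.3 Th fragment and 0.5 Th precursor tolerance, appropriate to a
unit-resolution QTRAP-class instrument; both are configurable.

Tags are searched in all six reading frames of each contig in both
orientations (ascending-m/z b-ladders read N→C, y-ladders C→N) with a
compiled-regex scan equivalent to the brute-force positionwise scan it is
tested against. Stop codons truncate candidates; segments shorter than 20
residues are discarded. Verification matches observed precursors to digest
products in m/z space at the observed charge (mirroring how the published
comparison was made); ties resolve to smallest |Δm/z|, then fewest missed
cleavages. Reconstruction overlays positioned peptides, errors out on any
residue conflict (naming the position), flags unresolved positions, and
reports the intact average mass of the longest contiguous segment.

## Tight-binding kinetics

The Morrison quadratic form is the fractional-activity solution of
E + I ⇌ EI mass balance when inhibitor and enzyme concentrations are
comparable, so depletion of free inhibitor cannot be neglected. The fit is
least squares on v/v0 with the enzyme concentration fixed at its
active-site-titrated value (an option to co-fit E exists, off by default),
parameterized in log K'ᵢ for positivity, unweighted residuals (no error
model is available for the source assays), initial guess
K'ᵢ ≈ I₅₀ − E/2, and scipy's trust-region least squares with tolerances
1e-12 (max 500 evaluations). Standard errors come from the Jacobian at the
optimum via the delta method on the log scale; Kᵢ = K'ᵢ/(1 + S/Km) is the
competitive correction. The fit is scale-equivariant in the rates.

Published Kᵢ values (0.05–94 nM across trypsin, chymotrypsin and
KLK5/7/14) are **simulation truths only** — the raw dose-response tables
were never published — so the tests are parameter-recovery experiments at
those magnitudes and enzyme regimes (e.g. 3 nM trypsin): zero-noise
recovery within 1%, and at 5% multiplicative noise over 200 replicates a
median relative error under 10% with ±2 SE interval coverage near 95%.

## Conservation and stability

Column scores follow the AMAS idea: 11 is reserved for strict gap-free
identity; otherwise the score counts how many of ten physico-chemical
properties are uniform (all residues have it, or all lack it) across the
column, capped at 10. The membership table is the Taylor/Zvelebil-style
classification (hydrophobic, positive, negative, polar, charged, small,
tiny, aliphatic, aromatic, proline); published descriptions of the score
name the properties but not the exact memberships, so the table is a
documented, swappable parameter. Gaps annihilate conservation by default
(score 0), with a gap-exclusion mode available.

ΔΔG = ΔG_mut − ΔG_wt (kcal/mol, residue→Ala) arrives as plain tables —
the energy-function machinery that produces them is an external producer,
not re-implemented. Ala/Gly positions are legitimately absent (no
informative mutation) and columns with zero observations are flagged
missing, never imputed as zero. Per-column means across homologs are
regressed on the conservation score by OLS; Pearson *r* is reported and
left undefined (flagged) under zero variance. The published correlation
(*r* = 0.73) is not desk-reproducible — it depends on an external energy
function and on homolog sequences available only graphically — so the
generator calibrates noise analytically (from the score variance and
per-column observation counts) to that target *r* and the test checks
recovery of the mean within ±0.03 over 200 seeds on a 52-column family.
The narrative ΔΔG bands used in reporting (>3.5 disulfide-class, >2
core-class, <1 tolerant) are configuration, not hard-coded thresholds.

## Trajectory statistics

Frames are superposed by least-squares rigid-body alignment of a selection
(default Cα) onto a reference frame; the rotation comes from scipy's
Kabsch solver and is cross-checked against an independent quaternion
(Kearsley) implementation. RMSF is the per-atom root of the time-mean
squared deviation from the time-mean position, averaged per residue. For
isotropic per-axis jitter σ the expectation is σ√3; with few fitted atoms
the superposition itself absorbs part of the fluctuation (≈√(1 − 6/3N)),
so the σ√3 check is run on trajectories that are aligned by construction.

Hydrogen bonds use a geometric criterion — donor–acceptor distance ≤ 3.5 Å
and donor–H–acceptor angle ≥ 150° when hydrogen positions exist, distance
only in heavy-atom mode — since the source figures fix only the 30%/85%
occupancy reporting classes, not the geometry; both cutoffs are echoed in
every report. Donor/acceptor typing is by residue/atom-name dictionaries
for the standard amino acids (backbone N/O plus polar side chains), waters
excluded by default. Close contacts count a residue pair when any
interatomic distance is below the cutoff (default 4.0 Å). Occupancies are
exact frame-count ratios, tested for equality with per-frame double-loop
oracles, and the mean number of interface H-bonds per frame equals the sum
of pair occupancies by construction. Trajectory I/O is multi-model PDB
only, at desk scale.

## Synthetic generators

All generators are seeded (`numpy.random.default_rng`) and byte-stable for
a given seed+configuration, and each returns a ground-truth manifest.

- **Transcriptome**: planted protein back-translated with uniform random
  synonymous codons, delimited by in-frame stop codons (so the translated
  ORF is exactly the planted mature chain), flanked by 30–200 nt UTRs on a
  random strand, among decoys of 300–3,000 nt at GC 0.4 (arbitrary,
  documented defaults) rejection-sampled to contain no 8-mer of the
  planted protein in any frame.
- **Spectra**: one spectrum per tryptic peptide, full singly charged b/y
  ladders with Gaussian m/z jitter (default 0.01 Th; 0.1 Th still leaves
  ≥95% of ladder peaks matchable at 0.3 Th), log-normal intensities, 30
  uniform decoy peaks in 50–1800 Th, precursor charge
  clip(round(length/7), 1, 5) matching the +2…+5 range of the published
  precursors.
- **Inhibition data**: v0 · morrison_fraction(E, I, Kᵢ(1+S/Km)) with
  multiplicative Gaussian noise (default CV 5%), on a geometric inhibitor
  grid spanning 1/50× to 50× of max(K'ᵢ, E) plus a zero point.
- **Trajectories**: independent per-frame Gaussian displacements with
  per-residue per-axis σ around a toy backbone (N/CA/C/O beads), optional
  per-frame random rigid motion (to exercise superposition) and an
  optional scripted donor–acceptor pair present in an exact fraction of
  frames.
- **ΔΔG tables**: linear in column score with homoscedastic Gaussian noise
  (no error model exists for the real producer), optional clamping to the
  empirically observed −0.2…5.4 kcal/mol band.

What passing these tests shows — and does not: the generators reproduce
the *statistical structure* each stage assumes (ladder spacings, Morrison
curvature, linear conservation–stability coupling, Gaussian fluctuations),
not real instrument physics (no isotope envelopes, retention time,
fragmentation efficiency), real assay systematics, or force-field-consistent
dynamics. Recovery on synthetic data therefore validates the estimators
and plumbing, not instrument- or force-field-level accuracy on real data.

## Problem sizes

Default test and acceptance runs use a 500-decoy transcriptome, 200
replicate kinetic fits, 200 ΔΔG seeds over 52 columns, 5,000-frame RMSF
trajectories (20 residues) and ≤100-frame oracle comparisons for H-bond
and contact occupancy — sizes chosen to exercise the asymptotics each
check relies on while keeping the whole suite fast on a laptop.

## Known limitations

No variable/localized modifications, isotope fine structure, database
search scoring or FDR machinery; exact-class tag matching (no mismatch
tolerance); no progress-curve (slow-binding) kinetics or mechanism
discrimination; no PBC unwrapping, solvent analysis or binary trajectory
formats; the conservation property table is one defensible choice among
several published variants.
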