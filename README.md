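# kunitzchar

Computational characterization of Kunitz-domain serine-protease inhibitors,
built around the two inhibitors ATPI-I and ATPI-II from the sea anemone
*Actinia tenebrosa*. The package re-implements, as a tested and reusable
pipeline, the desk side of a complete wet-lab characterization:

1. **Mass chemistry & digestion** (`kunitzchar.masses`) — monoisotopic and
   average peptide/protein masses, fixed modifications
   (carbamidomethyl-Cys, +57.02146 Da), charged-ion *m/z*
   ((M + z·1.00728)/z), and tryptic digestion (cleave after K/R, not
   before P, with missed cleavages).
2. **MS/MS identification** (`kunitzchar.spectra`,
   `kunitzchar.proteogenomics`) — theoretical b/y (and a/z) product ions,
   spectrum annotation, de novo sequence tags from same-series peak
   spacings, tag search in six-frame-translated transcriptome contigs, and
   mass-verified reconstruction of the full chain from overlapping matched
   peptides.
3. **Tight-binding kinetics** (`kunitzchar.kinetics`) — the Morrison
   quadratic model for fractional activity,
   v/v0 = 1 − [(E+I+K'ᵢ) − √((E+I+K'ᵢ)² − 4EI)]/(2E),
   fitted statsmodels-style: `MorrisonKiModel(...).fit()` returns a results
   object with Kᵢ = K'ᵢ/(1+S/Km), its standard error, and a `summary()`.
4. **Conservation & stability** (`kunitzchar.conservation`) — AMAS-style
   physico-chemical column scores 0–11 for a Kunitz multiple alignment,
   score binning (9–11 / 5–8 / 2–4 / 0–1), per-column averaging of
   alanine-scan ΔΔG tables across homologs, and the conservation-vs-ΔΔG
   linear regression (Pearson *r*).
5. **Trajectory post-processing** (`kunitzchar.trajectory`) — Kabsch
   superposition, per-residue Cα RMSF, geometric hydrogen-bond occupancy
   with the 30%/85% reporting classes, and <4 Å close-contact occupancy,
   from multi-model PDB trajectories.
6. **Synthetic data** (`kunitzchar.simulate`) — seeded generators for every
   input: transcriptomes with a planted coding sequence among decoys,
   b/y-ladder spectra with noise, Morrison dose-response curves,
   Gaussian-fluctuation trajectories, and conservation-correlated ΔΔG
   tables calibrated to a target *r*.

It is aimed at protein biochemists and bioinformaticians who want each of
these steps as an importable, unit-tested primitive rather than a chain of
vendor GUIs.

## Worked example

Reconstruct ATPI-I from synthetic evidence and fit a Kᵢ:

```python
import kunitzchar as kc
from kunitzchar.datasets import ATPI_I_CHAIN
from kunitzchar import simulate as sim
from kunitzchar.pipeline import run_identification

contigs, _ = sim.make_transcriptome(ATPI_I_CHAIN, n_decoys=500, seed=11)
spectra, _ = sim.make_spectra(ATPI_I_CHAIN, seed=12)
report = run_identification(spectra, contigs)
print(report["best_candidate"], report["coverage"],
      report["intact_average_mass_Da"])
# planted_contig|frame4|off55 1.0 6719.43

df, _ = sim.make_inhibition_data(Ki_nM=1.6, E_nM=0.5, noise_cv=0.0, seed=1)
res = kc.MorrisonKiModel.from_dataframe(
    df, enzyme_nM=0.5, substrate_uM=100, km_uM=200, v0=1.0).fit()
print(res.summary())
```

```
Morrison tight-binding inhibition fit
=============================================
observations:        13
enzyme (fixed):      0.5 nM
substrate / Km:      100 / 200 uM
converged:           True
Ki_app:              2.4 +/- 8.5e-15 nM
Ki:                  1.6 +/- 5.7e-15 nM
residual SD (v/v0):  1.16e-15
```

The identification report says the planted contig was the unique candidate
with tag evidence, every observed precursor matched its theoretical digest
peptide (residue coverage 1.0), and the assembled 60-residue chain has the
intact average mass 6719.43 Da expected for the reduced, unmodified-Cys
chain. The noiseless kinetic fit recovers the simulated Kᵢ of 1.6 nM
exactly, with the apparent constant 2.4 nM reflecting the 1 + S/Km
substrate correction.

A single console script exposes each stage
(`kunitz-char mass|digest|tags|verify|identify|ki|conserve|traj|characterize|simulate`);
run `kunitz-char --help`.

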