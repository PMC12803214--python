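# hdxstab

Differential hydrogen-deuterium exchange mass spectrometry (HDX-MS)
analysis of small-molecule **kinetic stabilizers** of immunoglobulin light
chains — the proteins whose misfolding, aberrant proteolysis and
aggregation cause AL amyloidosis. Stabilizers bind the native light-chain
dimer (one molecule per dimer, at the V_L–V_L interface) and slow the
conformational excursions that enable amyloid formation; HDX-MS reads that
stabilization out as reduced deuterium uptake.

The package is aimed at structural mass spectrometrists and protein
biochemists who have peptide-level centroid data (DynamX-style state
tables or equivalent) and want a scripted, reproducible path from
centroids to residue-level protection maps, binding titration fits, and
proteolysis statistics.

## What it computes

- **Back-exchange-corrected deuteration.** Uptake = m_t − m_0;
  %D = 100 (m_t − m_0)/(m_maxD − m_0) against a maximally deuterated
  control, which cancels label loss during analysis exactly.
- **Residue-level maps on a shared alignment.** Peptide %D is reduced to
  single-residue level (coverage-weighted average, or bounded least
  squares), projected onto master-alignment coordinates so different
  light chains are comparable, with condition difference maps
  (Δ%D = stabilizer − vehicle; protection is negative) and a trapezoidal
  exchange-AUC summary over log10(time).
- **PLIMSTEX titration fits.** Deuterium uptake of a reporter peptide vs
  ligand concentration at fixed labeling time, fitted to the unimolar
  protection model uptake(L) = D0 + ΔDmax·L/(EC50 + L) (statsmodels-style
  `TitrationModel.fit() → BindingFit` with standard errors and
  `summary()`); an exact 1:1 dimer:ligand depletion model is available.
- **Limited-proteolysis kinetics.** Single-exponential decay fits of
  fraction-intact timecourses, trapezoidal AUC, single-timepoint
  protection deltas, and Pearson correlation of per-protein proteolysis
  vs HDX summaries.
- **A calibrated forward simulator** of the whole experiment (EX2
  exchange under protection factors, ligand coupling with fast or
  slow/bimodal kinetics, centroid noise, maxD controls, Poisson-binomial
  isotope envelopes, proteolysis decay) providing ground truth for every
  stage.

## Worked example

Round-trip a PLIMSTEX titration at the reference parameters of the
full-length AL light chain: simulate a noiseless titration on the 2-fold
serial dilution grid 0.095–25 μM (plus vehicle) at 90 min labeling, then
fit it back.

```python
from hdxstab.examples import reference_titration_fit

fit = reference_titration_fit("AL LC")
print(fit.summary())
```

```
PLIMSTEX binding fit
==============================================
model:            hyperbolic
n concentrations: 10

parameter            value     stderr
----------------------------------------------
D0 (Da)               3.73   5.25e-14
dDmax (Da)          -1.406   5.95e-14
EC50 (uM)             0.65   1.13e-13
----------------------------------------------
dD at top concentration (Da): -1.37 (|dD| = 1.37)
residual norm (Da):           1.7e-13
```

Reading the numbers: without ligand the reporter peptide (alignment
residues 101–110, spanning CDR3/FR4 at the dimer interface) takes up
3.73 Da of deuterium in 90 min. Stabilizer binding protects it: uptake
falls by 1.37 Da at the top of the titration (25 μM), with a protection
midpoint EC50 of 0.65 μM. ΔDmax (−1.406 Da) is the asymptotic change the
hyperbola extrapolates to at saturation — slightly larger than the change
observed at 25 μM because the top concentration does not fully saturate
the site. The near-zero standard errors and residual norm reflect that
this is a noiseless round trip; with real (or simulated noisy) data they
report fit uncertainty.

The same pipeline is scriptable from the shell:

```sh
hdxstab --seed 3 simulate --out data/          # synthetic dataset + ground truth
hdxstab exchange data/state_table.csv --out uptake.csv
hdxstab reduce   data/state_table.csv --out residues.csv
hdxstab plimstex data/titration.csv   --out fit.json
hdxstab proteolysis data/proteolysis.csv --out prot.json
```

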