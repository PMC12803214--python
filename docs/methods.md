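# Methods

## Scope and model

`hdxstab` analyses differential hydrogen-deuterium exchange mass
spectrometry (HDX-MS) experiments that probe the stabilization of
immunoglobulin light chains (LCs) by small-molecule kinetic stabilizers,
together with the accompanying PLIMSTEX binding titrations and
limited-proteolysis kinetics. The package also contains a forward
simulator of the whole experiment, so every analysis stage can be tested
against known ground truth without access to raw instrument data.

### Back-exchange-corrected deuteration

The observables per peptide are three centroid masses: undeuterated (m0),
after labeling time t (mt), and a maximally deuterated control (mmaxD).
Uptake is mt − m0 (Da) and percent deuteration is

    %D = 100 (mt − m0) / (mmaxD − m0).

Because deuterium loss during quench/digestion/chromatography scales both
differences by the same retention factor, the ratio cancels back exchange
exactly. This identity is the pipeline's central correctness property and
is tested to 1e-9 on noiseless simulated data over random retentions in
(0.3, 1]. Values slightly outside [0, 100] are preserved; beyond
[−5, 105] they are flagged `out_of_range` and excluded from residue
reduction by default (centroid noise of ±0.20 Da on small maxD
denominators can overshoot; the window is a conservative multiple of that
noise). Replicate dispersion is reported as the range (max − min),
matching how duplicate HDX measurements are usually displayed; the SD is
added when n ≥ 3.

### Exchange model in the simulator

Per-residue EX2 kinetics with protection factors:

    D_i(t) = f_D (1 − exp(−(k_int,i / P_i) t)),

with f_D = 0.9 by default (a 10-fold dilution into D2O labeling buffer),
k_int from the standard poly-DL-alanine reference coefficients
(acid/base/water terms, neighbouring-side-chain factors, Arrhenius
temperature corrections from 293 K; table versioned as
`polyDLA-293K-1`), and ln P_i ≥ 0 per residue. Prolines and the protein
N-terminal residue never report; the first two residues of every peptide
are excluded from peptide-level uptake (their amide label back-exchanges
too fast to survive analysis). This exchangeability convention is the
field default, is isolated in one function (`reporter_residues`), and is
shared by the simulator and the residue reducer. All deterministic tests
use the uniform-rate override so no frozen expectation depends on
individual coefficient-table entries.

Observation model per peptide: true uptake = Σ over reporters of
D_i(t) × 1.00628 Da (the H→D mass increment, configurable); observed
mt = m0 + r·(true uptake) + N(0, σ) with σ = 0.20 Da by default (the
stated precision of peptide-level deuterium determination) and r the
per-peptide back-exchange retention. maxD controls are generated
noiseless with the same r — per-replicate maxD variation is supported but
off by default. m0 is the peptide's monoisotopic mass (pyteomics).

Ligand coupling multiplies P_i by exp(Δln P_i) in the bound state
(Δln P ≥ 0, zero outside the binding footprint; stoichiometry fixed at
one ligand per LC dimer). Two kinetic limits are provided: fast exchange
(one population at the occupancy-averaged rate) and slow two-population
(weights 1−θ, θ), which produces bimodal envelopes; the two limits agree
only as Δln P → 0, which is asserted as a convergence test. Occupancy θ
follows the phenomenological hyperbola θ = L/(EC50 + L) by default —
deliberately, because PLIMSTEX midpoints here are potency measures, not
dissociation constants — with an exact 1:1 dimer:ligand mass-balance
(quadratic depletion) mode for thermodynamic use; the two converge as
total protein → 0 (tested).

Isotopic envelopes are Poisson-binomial over per-site deuteration
probabilities, spaced by deuteron_mass/charge; mixture spectra are
weighted sums.

### PLIMSTEX fitting

`TitrationModel`/`BindingFit` follow the statsmodels Model/Results idiom.
The default model is uptake(L) = D0 + ΔDmax·L/(EC50 + L), fitted by
Levenberg-Marquardt (lmfit) after averaging replicates per concentration
(unweighted for duplicates). Initialization is parameter-free: D0 from
the lowest concentration, ΔDmax from the span, EC50 from the
concentration nearest the half-change. Asymptotic standard errors come
from the fit covariance. Flat series converge with ΔDmax ≈ 0 and are
flagged unidentifiable rather than raising. The reported `delta_uptake`
is the signed change between the highest tested concentration and D0 —
the convention in which titration endpoints are quoted — and differs from
the asymptote ΔDmax unless the top of the titration saturates the site;
its magnitude is reported alongside because endpoint changes are often
printed unsigned. Fitting absolute uptake with D0 free is equivalent to
fitting the change ΔD up to an offset.

The simulator's titration calibrator inverts this convention: given
(D0, ΔD at L_max, EC50) it solves the EX2 closed form for uniform
free/bound per-residue protection over the peptide's reporters with the
bound-state asymptote at D0 + ΔD/θ(L_max), using the slow two-population
coupling whose centroid is exactly linear in occupancy. The generated
series therefore follows the hyperbola exactly and a noiseless round trip
recovers the generating parameters to machine precision (asserted at
3 significant figures, and to 0.1 % as a property over random parameter
sets with the midpoint inside the 0.095–25 μM grid). Under the stated
centroid noise (SD 0.20 Da, duplicates) the median recovered midpoint
over 100 seeded titrations stays within 20 % of truth (asserted; measured
≈ 0.4 % for a midpoint of 1.8 μM).

The bimodality score of `mixture_centroid` is a two-segment split
statistic: 1 − SSE(best contiguous two-centroid split)/SSE(single
centroid) on the intensity-weighted m/z profile. It is reported, never
thresholded; unimodal envelopes score well below separated mixtures.

### Residue reduction and difference maps

Peptide %D is reduced to residue level two ways:

- `weighted_average` (default): each residue's value is the mean of the
  %D of the peptides in which it is an exchangeable reporter, weighted by
  1/(number of reporters in the peptide). This is transparent,
  deterministic and linear, but it is a smoother: re-averaging the
  residue map over a peptide's reporters reproduces the peptide %D
  exactly only for locally uniform signal. That is the intended
  trade-off for a visualization/comparison surface.
- `nnls`: per condition and time, bounded least squares (scipy
  `lsq_linear`, BVLS) on %D(peptide) = mean of residue values over its
  reporters, constrained to [0, 100]. On consistent inputs it attains
  zero residual and reproduces every peptide %D; it is cross-checked
  against an independent SLSQP minimiser to 1e-6.

Neither method models exchange thermodynamics (no ΔG fitting); reduction
here serves comparison between proteins on the shared alignment. Both
protomers of an LC dimer are assumed equivalent and share one map.
Residues covered by no peptide are uncovered, survive round trips as
explicit gaps, and are never imputed.

Coordinates: sequential numbering is 1-based with inclusive intervals;
alignment numbering is 1-based over the master alignment (219 columns for
the LC alignment used in the examples, variable domain in columns 1–113).
Gap columns map to nothing; alignment→sequential interval mapping drops
gap columns, sequential→alignment may return a longer interval.

Difference maps are cell-wise %D(A) − %D(B) where both conditions are
covered; stabilizer protection appears as negative Δ%D; the operation is
antisymmetric under swapping conditions.

The exchange AUC summary integrates %D per residue over log10(time in
seconds) by trapezoids and sums over residues — by default those covered
at every time, or an explicit common-coverage set when comparing
experiments (`common_coverage`). The log axis is chosen because labeling
times are log-spaced (10 s to 16 h); a linear axis, available as an
option, would be dominated by the longest timepoint. Whether to integrate
over time and sum over residues, or the reverse, is a genuinely open
choice; the time-integral reading is adopted as it yields a per-residue
stability density before summation.

### Proteolysis kinetics

Intact-fraction decay is fitted as F(t) = A·exp(−k t) with A free in
[0.8, 1.2] (gel-densitometry baselines drift; a plateau term is
deliberately omitted) and k ≥ 0, via lmfit. Rising timecourses are
flagged non-convergent/implausible rather than raising, since not every
protein's data supports a rate. The fit-free AUC (trapezoids over hours)
and the single-timepoint protection delta (stabilized − vehicle fraction)
complement the rate. Times are hours throughout proteolysis while HDX AUC
uses log10 seconds; the cross-method comparison correlates unitless
per-protein summaries, so the axis mismatch is harmless. Pearson r with
two-sided p (scipy) uses pairwise deletion of missing values and rejects
zero-variance inputs.

Parameter-recovery behaviour: at the simulator's noise (SD 0.05 on
fractions) a per-draw 5 % rate error is not attainable — the measured
per-draw median relative error is ≈6 % with 16 log-spaced timepoints over
24 h. The recovery suite therefore asserts what a recovery suite can
show: the central tendency of recovered/true rate ratios within 5 % of
unity (measured bias ≈1.7 %) and no spurious non-convergence, over 200
seeded simulations with k ∈ [0.05, 2] h⁻¹.

## What the simulator does and does not emulate

Emulated: EX2 exchange under per-residue protection, the six-point
log-spaced labeling schedule, 90 % label fraction, per-peptide back
exchange with noiseless maxD controls, ±0.20 Da centroid noise,
ligand-coupled protection with 1:1 dimer stoichiometry, bimodal spectra
for partially bound populations, exponential proteolytic decay, and full
seed reproducibility.

Not emulated: EX1 kinetics beyond the two-population mixture,
chromatography/ionization artifacts, overlapping charge states, digestion
(peptide maps are user-specified), carry-over, pD/solvent effects of DMSO
on intrinsic rates, and inter-replicate maxD variation (supported but off
by default). Passing tests therefore demonstrate the correctness of the
analysis algebra and estimators under the stated noise model, not
robustness to every instrument pathology in real data.

## Problem sizes and determinism

All simulations in the tests and the acceptance script run on a
10-residue peptide (8 reporters), 10-concentration titrations, and
timecourses of at most ~2000 points; the Monte-Carlo suites use 100–200
seeded draws. The whole test suite completes in a few seconds on one
CPU. Every random draw flows from an explicit `numpy.random.Generator`
seed; seeded runs are bit-reproducible (tested).

## Known limitations

- The synthetic alignment row in `hdxstab.examples` reproduces published
  coordinate conventions (alignment columns 101–110 = sequential 98–107
  of the AL light chain) with deterministic filler sequence; it is not a
  real LC sequence.
- The weighted-average reducer's smoothing behaviour (above) means
  difference maps built from it attenuate sharp single-residue features
  that nnls would resolve.
- The intrinsic-rate table affects only simulator realism, not analysis
  results; its entries follow the standard literature parameterization
  but are not re-validated here.
- The depletion-aware binding model treats the protein as a fixed pool of
  binding-competent dimers; monomer-dimer linkage is not modelled
  (ligand-induced dimerization appears in the data only through the
  phenomenological midpoint).
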