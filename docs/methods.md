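# Methods

`multibiodx` implements a discriminative analysis of schizophrenia (SZ)
versus healthy controls (HC) that integrates three biological modalities —
resting-state EEG brain-network attributes, gut-microbiota abundances and a
routine blood panel — into a multi-classifier machine-learning grid.  The
clinical data behind such analyses are not publicly available, so the
package ships a synthetic-cohort generator with the statistical structure
the analysis assumes; everything downstream of the generator is the analysis
proper and makes no reference to how its inputs were produced.

## EEG signal chain

**Preprocessing.**  Recordings are 16-channel (10/20 montage Fp1...T6),
1000 Hz, nominally 180 s eyes-closed rest.  The software contract is a
0.1–45 Hz zero-phase bandpass; segmentation into non-overlapping 2-s
epochs; amplitude-based epoch rejection (default threshold 100 µV peak on
any channel, an automated stand-in for manual artifact screening); and a
filter bank of seven subbands — delta 1.5–4, theta 4–8, alpha1 8–10,
alpha2 10–13, beta1 13–20, beta2 20–30, gamma 30–45 Hz — plus the 0.1–45 Hz
"whole" band.

Filters are Hamming-window linear-phase FIRs with the common
order rule N ≈ 3.3/Δf_norm, transition width 25% of the band edge floored at
0.25 Hz, applied forward–backward so phase is untouched (PLV consumes
phase).  At these orders the impulse response of the low-frequency bands is
several seconds long, so band filters run on the *continuous* recording and
the signal is epoched per band afterwards; the rejection mask is decided
once on the broadband epochs and applied to every band.  `band_decompose`
also accepts epoched input, capping the order at a third of the epoch
length (documented wider transitions) for callers that need it.

**Connectivity.**  Instantaneous phase φ(t) is the angle of the analytic
signal (Hilbert transform); the phase-locking value of a channel pair is

    PLV = | (1/N) Σ_j exp( i (φ_x(jΔt) − φ_y(jΔt)) ) |,

computed within each 2-s epoch after discarding 5% of samples at each edge
(Hilbert edge effects), then averaged across epochs.  PLV ∈ [0, 1]; for N
independent uniform phases E[PLV] = √π/(2√N) (Rayleigh resultant length),
the estimator's noise floor.

**Brain networks.**  Each band's 16×16 PLV matrix is binarized over a cost
grid: at cost c the k = round(c·120) strongest off-diagonal weights become
edges (half-away-from-zero rounding; ties broken by weight descending then
row-major pair index, so edge sets are nested in c).  The grid is
0.34 ≤ c ≤ 0.73 in steps of 0.01 — the small-world regime whose lower end
tracks the 2·ln N/N ≈ 0.347 estimability guideline for N = 16.  Graphs are
binary and undirected.

Per cost we compute global clustering aCp, characteristic path length aLp,
global efficiency aEg, local efficiency aEloc, and the small-world indices
aGamma = aCp/⟨aCp_null⟩, aLambda = aLp/⟨aLp_null⟩, aSigma = aGamma/aLambda
against 100 degree-matched Maslov–Sneppen rewired nulls (≥ 10·m successful
double-edge swaps each; connectedness not enforced; ensemble means, not
medians).  Nodal attributes are clustering aNCp, mean distance aNLp,
efficiency aNe, neighbourhood-subgraph efficiency aNLe and degree aDc.
Conventions, since several coexist in the literature: disconnected pairs are
excluded from path-length means and contribute zero to efficiency sums;
nodes with fewer than two neighbours have aNCp = aNLe = 0.  These choices
keep aLp finite at low cost and are verified against an independent
brute-force oracle (Floyd–Warshall distances, explicit triangle counts) and
against networkx in the tests.

Each attribute-versus-cost curve is collapsed by trapezoidal area under the
curve; non-finite points are dropped, and a curve with fewer than two finite
points yields a missing feature that the completeness filter later removes.
Feature names are `band_attr` / `band_attr_channel` (e.g. `theta_aNLe_T6`):
8 bands × 7 global = 56 plus 8 × 5 × 16 = 640 nodal names per subject.

## Microbiota and blood features

The taxa table (171 named taxa, zero = absent) passes a prevalence filter:
a taxon missing in *more than* 85% of participants is removed.  Abundances
are used directly as features — no compositional transform, rarefaction or
diversity summarisation.

The blood panel holds five cell counts (WBC, NEU, LYM, PLT, MON), four
derived inflammation indices — NLR = NEU/LYM, PLR = PLT/LYM, MLR = MON/LYM
and the systemic immune-inflammation index SIII = PLT·NEU/LYM (the standard
definition; the ratio columns are always recomputed from the counts) — and
three serum markers (SOD, homocysteine, CRP).

Cohort demographics are compared with a Welch two-sample t test (age,
education; Welch rather than pooled because variances are not assumed equal
— at near-equal variances the difference is < 0.01 in t) and a Pearson
chi-square without continuity correction for sex, reported together with its
signed square root (the two-proportion z statistic) for comparability with
reports that quote the root.

## The classification framework

Four input sets — GM (filtered taxa), Blood (12 features), EEG (AUC
features after a completeness filter that drops any feature missing for any
participant), and Combined (their concatenation) — are crossed with feature
selection in {None, PCA, RFE, ANOVA}, classifiers {SVM, RF, LDA, LR, KNN}
and CV schemes {10-fold, 5-fold, 3-fold, LOO}.  PCA and RFE are excluded
for the 12-dimensional blood panel, giving 3·5·4·4 + 1·5·2·4 = 280
configurations.

Subjects are split 3:1 into training and an independent hold-out test set,
stratified by group (per class, ⌊n/4⌋ subjects to test).  All transforms —
z-scoring, ANOVA F-tests (keep p < 0.05), PCA (components explaining ≥ 95%
of training variance, on standardized features), RFE (linear SVM,
eliminating to 50% of features) — are fit on training subjects only and
refit inside every CV fold.  Classifier defaults: linear SVM with C = 1
(linear so the winning no-selection SVM supports weight-based feature
ranking), RF with 500 trees, LDA, L2 logistic regression with C = 1, KNN
with k = 5; z-scoring precedes every classifier except the scale-invariant
random forest; no nested hyperparameter tuning.  Hold-out performance is
accuracy, sensitivity (SZ positive), specificity, and the ROC/AUC from the
continuous decision scores (the trapezoidal AUC equals the Mann–Whitney
concordance, asserted in the tests).

Significance uses a label-permutation test: labels are shuffled *before*
the hold-out split and the entire pipeline is rerun per permutation
(a full-pipeline null); p = #(permuted accuracy ≥ observed)/n_perm, the
literal proportion, which can be zero; an (r+1)/(n+1) variant is available
behind a flag.  With small test sets the discreteness of accuracy makes
this p conservative (ties count against the observed model), so under the
null its mean sits somewhat above 0.5.

Feature ranking takes |coefficients| of linear models on standardized
features (or RF impurity importances), maps them through feature-preserving
selectors, sorts descending with name-order tie-breaks, and truncates to
⌈5% of the feature count⌉ — 34 features for a 663-column combined table.
Ranking after PCA is refused (weights are not attributable to inputs).
The best model per input set is selected by hold-out AUC; CV and test
accuracy are both reported, and best-of-grid values on a ~24-subject
hold-out carry selection optimism.

## The synthetic cohort

No distributional information is available for any modality, so all
distributions below are explicit, configurable stand-ins; a single root
seed feeds named substreams (cohort/eeg/taxa/blood) so modalities can be
regenerated independently.

* **Demographics** — age ~ Normal(42, 13²) truncated positive in both
  groups; education Normal(14.2, 3.6²) in HC vs Normal(11.6, 3.4²) in SZ;
  sex Bernoulli(0.475 male).  Cosmetic covariates; nothing downstream
  conditions on them.
* **EEG** — per band, each channel mixes a shared band oscillator (common
  frequency and slow phase jitter across the coupled set, mixing weight
  √c) with a channel-private oscillator at a distinct frequency drawn from
  a shuffled grid spanning the band (weight √(1−c)); bands are summed with
  1/f-flavoured amplitudes plus white noise.  c = 1 forces PLV → 1; c = 0
  lets phases drift apart.  Group effects are coupling deltas: SZ shows
  reduced theta and alpha2 coupling over temporo-parietal channels and a
  mild beta2 increase, mirroring the band/region pattern reported for SZ
  resting networks.  No volume conduction, reference effects or electrode
  forward model are simulated — PLV levels are controllable but their
  absolute values should not be read as physiological.
* **Microbiota** — zero-inflated log-normal: 77 "core" taxa at presence
  probability 0.9 and 94 rare taxa at 0.05, so the prevalence filter
  retains ≈ 77 of 171; SZ log-fold-changes on six named genera
  (Lactobacillus +1.8, Haemophilus +1.4, Prevotella −1.4, Collinsella
  +1.0, Megamonas +1.2, Clostridium +1.0).
* **Blood** — truncated-normal counts and serum markers with SZ shifts in
  the directions reported for chronic SZ (higher WBC/NEU/MON/CRP/
  homocysteine, lower SOD and LYM); ratios recomputed from counts.

**Calibration.**  Effect magnitudes were calibrated against the reported
single-modality operating points (hold-out accuracy ≈ 71% for microbiota,
≈ 83% for blood, ≈ 79% for EEG) by measuring single-modality accuracy of a
linear SVM at the reference cohort size (49 + 50); the defaults above reproduce ≈ 0.70
/ 0.78 / 0.78 with the combined set at ≈ 0.88–0.92.  The multimodal-gain
experiment (combined strictly beating the best single modality in ≥ 70% of
50 replicates) uses cohorts of 100 per group: at the reference n = 99 the
24-subject hold-out quantizes accuracy in 4.2-point steps, so the expected
~5-point gain ties in roughly a quarter of replicates; a 50-subject
hold-out resolves it.  For experiments that need many cohort replicates the
EEG modality is drawn from `simulate_eeg_summary_features` (Gaussian
network-feature surrogates, 0.85 SD shift on 10 of 60 features); the full
signal→PLV→graph→AUC chain remains the tested path wherever the network
stage itself is under scrutiny.

**What passing tests do and do not show.**  The synthetic cohort has
independent subjects, Gaussian-ish marginals, no batch effects, no
medication or diet confounds, no volume conduction, and group effects
placed exactly where the analysis looks for them.  Green tests therefore
demonstrate that the pipeline measures what it claims to measure and is
statistically calibrated (chance-level behaviour, permutation uniformity,
no selection leakage) — not that real EEG/microbiome/blood data would
yield the reported real-data performance.

## Numerical and design notes

* Cost-grid edge counts use half-away-from-zero rounding; nestedness across
  costs is guaranteed by the fixed pair order and asserted as an invariant
  (aEg is non-decreasing along the nested sequence).
* Rewiring gives up (with a warning and a `degenerate` flag) on graphs with
  no swappable edge pair, e.g. complete graphs.
* PLV is averaged over all epoch samples after edge trimming; the
  alternative of dropping one endpoint sample changes the value by O(1/N)
  and is ignored.
* Epoch rejection happens before band decomposition (on the broadband
  signal), configurable.
* An all-zero signal has undefined phase and is rejected; an epoch set with
  zero surviving epochs raises rather than propagating empty PLVs.
* Problem sizes in the test-suite and acceptance-script experiments (6–12
  subject smoke cohorts, 6–10 s recordings, 2–8 nulls per cost, 99–200
  subject classification cohorts) are chosen to keep a full run in minutes
  on one CPU while leaving every assertion at its stated tolerance; the
  full-scale defaults (180 s, 100 nulls) remain the package defaults.

## Known limitations

* Binary graphs only; no weighted metric variants, betweenness or
  modularity.
* No ICA artifact correction or re-referencing; rejection is amplitude-only.
* The taxa table is generated directly — no 16S read simulation, taxonomy
  assignment, or compositional treatment.
* Permutation p values inherit the discreteness of small hold-out sets.
* Best-model selection by test AUC (the tie to the reported tables) uses
  the same hold-out it reports, a mild optimism shared by the emulated
  design.
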