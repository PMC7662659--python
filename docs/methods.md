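# Methods

This note records the models, conventions and numerical choices behind
`walnutmir`, in the spirit of a chemometrics methods section.

## Data model and sampling design

A dataset is an absorbance matrix X (n samples × p wavenumbers) with a
strictly monotonic axis in cm⁻¹ and two nested labels per sample: a
geographic origin and a variety, every variety belonging to exactly one
origin.  The packaged reference design holds 10 varieties in 4 provinces
with per-variety sizes (20, 19, 19, 20, 20, 20, 20, 16, 18, 20) — 192
samples — and per-variety training counts (13, 13, 13, 13, 13, 13, 13,
10, 12, 13), i.e. 126 train / 66 test.

The generic split rule is round-half-up(2n/3) per variety, with sample
membership drawn uniformly under a seed.  The reference design's printed
counts are *not* reproducible by any single rounding of 2n/3 (13/6 for
n = 19 rounds .67 up while 10/6 for n = 16 rounds .67 down), so the design
table carries explicit training counts and `stratified_split` accepts
them as an override.  This is a deliberate choice: the published
partition is data, not a formula.

## Wavelet pre-treatment

Each spectrum is decomposed with Daubechies Db3 to level 4 (symmetric
boundary extension).  The noise scale σ is estimated once per spectrum as
median(|d₁|)/0.6745 from the finest detail level d₁ — for a smooth
band spectrum d₁ is essentially pure noise — and every detail level is
shrunk with the universal threshold σ·√(2 ln N); approximation
coefficients are untouched.  Soft shrinkage is the default; hard
thresholding is available and preferable when the signal itself has
sharp, high-frequency content (a pure tone leaks into mid-level details,
where the soft rule's constant bias can exceed the noise removed — the
test suite demonstrates this on a sine).  Denoising precedes nothing: the
pipeline order is trim → denoise, so the noisy spectral ends never enter
the transform.

## PLS engine

`pls_core` implements PLS2 with sequential NIPALS-style deflation.  The
inner relation — the fixed point of the NIPALS power iteration, i.e. the
leading left singular vector of XᵀY — is solved exactly per component
through the q×q eigenproblem of (YᵀX)(XᵀY) (q = number of response
columns, ≤ 10 here).  This is algebraically the converged NIPALS solution
but deterministic and an order of magnitude faster, which matters because
the GA evaluates tens of thousands of cross-validated fits.  Regression
coefficients are B = W(PᵀW)⁻¹Qᵀ; because PᵀW is triangular the
per-component coefficients are nested, B_a = B_{a−1} + r_a q_aᵀ, and
cross-validation scores every component count A = 1…A_max from a single
fit per fold.  best_A is the smallest A within 1e−12 of the minimum
RMSECV (parsimony tie-break).  Leave-one-out is the default fold scheme;
k-fold (interleaved assignment, so class-ordered data spreads across
folds) is used inside the GA for speed.

## UVE

n_artificial noise columns (default: as many as real variables), drawn
uniform(0,1) and scaled to 1e−2 of mean |X|, are appended to X.  The
amplitude is immaterial in theory — stability is scale-free — and the
small value only protects conditioning.  Leave-one-out PLS with 12 latent
variables (capped by fold size) collects per-fold coefficient vectors;
stability is mean/std over folds, computed per response column of the
one-hot Y and aggregated per variable as the signed entry of largest
magnitude.  The cutoff is ±max |stability| over the artificial columns
(multiplier 1); real variables inside the band are discarded.  A zero
coefficient spread yields ±∞ stability: a real variable is then retained,
an artificial one widens the cutoff to infinity.

## SPA

Chains are grown on the raw (uncentred) training columns: starting from
every candidate column, repeatedly add the column whose projection onto
the orthogonal complement of the selected span has the largest norm;
near-zero residuals terminate the chain (rank deficiency).  Each chain
prefix of size k = 5…30 is scored by leave-one-out RMSE of an
intercept-augmented linear regression on the subset, computed in closed
form from one nested QR factorisation per chain (hat-diagonal trick).
The (start, k) prefix with the global minimum RMSE wins.  In the UVE-SPA
chain the candidate pool is the UVE-retained set; if fewer than k_min
variables survive UVE the call fails with advice rather than guessing.

## GA-PLS

Binary chromosomes over genes; above 500 variables, adjacent windows of
equal width are averaged into at most 500 genes and selected genes map
back to all their member wavenumbers on output.  Per run: population 30
initialised at ~5 % gene density (minimum one gene), tournament selection
of size 2, uniform crossover with probability 0.5, per-bit mutation 0.01,
elitism 1, all-zero chromosomes repaired by switching on a random bit;
1000 chromosome evaluations per run, 10 runs by default at this scale.
Fitness is the minimum over A of 5-fold RMSECV of PLS on the encoded
subset (duplicate chromosomes are cached).  Each run contributes its
final population's per-gene selection counts with weight 1/best-RMSECV;
the weighted average is the selection frequency.  The RMSECV trace adds
genes in decreasing-frequency order (index tie-break); three marks are
placed on it: *global* = argmin, *suggested* = smallest size within one
standard error of the minimum (SE over fold RMSEs at the argmin), and
*better* = smallest size within 2 % of the minimum.  The returned subset
is the *better* model's genes.  The mark definitions are house
conventions — the terms are standard but their thresholds are not.

## Classifiers

All five sit behind one `fit_classifier(X, labels, spec)` /
`model.predict(X)` contract with a single headline parameter each.

* **ELM** — hidden layer sigmoid(XW + b) with seeded uniform(−1, 1)
  weights; output weights by Moore–Penrose pseudoinverse against one-hot
  targets.  `parameter="auto"` sweeps hidden sizes 1…n_train and keeps
  the smallest size achieving the minimum training error.
* **RF** — bagged CART trees (sklearn trees, per-split feature subsets of
  size √p) with majority vote across trees and lowest-index label on
  ties.  The tree learner is an adapter; the vote rule is ours.
* **RBF** — centers by seeded k-means; spread defaults to the median
  pairwise center distance; Gaussian design matrix with bias column,
  linear output weights by pseudoinverse, argmax decision.
* **PLS-DA** — one-hot targets through the PLS engine; label by argmax.
  The classical acceptance flag |ŷ_k − y_k| < 0.5 is computed per
  response column (`threshold_accept`), but accuracy is always reported
  from argmax: with more than two classes the threshold rule alone can
  abstain or multi-assign.
* **BPNN** — one sigmoid hidden layer, sigmoid outputs, full-batch
  gradient descent on MSE at learning rate 0.6, at most 1000 epochs,
  stop at MSE ≤ 10⁻⁵, seeded uniform(−0.5, 0.5) initialisation.  Inputs
  are min–max scaled to [−1, 1] inside the model (the common
  feed-forward default; raw absorbance magnitudes train far too slowly
  at a fixed learning rate).  Training on the full spectral range is
  refused at the task level — only selected subsets feed the BPNN.

ELM/RF/RBF/BPNN are exactly reproducible given (seed, data, spec).

## Evaluation

PCA is a column-mean-centred SVD of the pre-treated spectra (no
autoscaling — absorbance units are homogeneous); explained percentages
come from the full singular spectrum.  Per-class accuracy is recall
(confusion diagonal over row sum); overall accuracy is trace over total;
both are rounded to two decimals for reporting while confusion matrices
keep full integer counts.  `run_task` executes one (task, variable input,
classifier) cell: trim → denoise → subset (for within-origin tasks) →
split by the stored partition → fit the selection on training rows only →
train → score the held-out test rows.  Selections are fitted per (task,
method) and shared across classifiers by the pipeline driver.

## Synthetic data

A variety template is Σ amplitude·origin-mult·variety-mult·G((ν − c −
shift)/σ) over a fixed band table (Gaussian by default, Lorentzian
available); each sample adds a random linear baseline (offset
uniform(−0.03, 0.03), slope uniform(−0.04, 0.04) across the axis) and
i.i.d. Gaussian noise (σ = 0.02 by default).  Origin effects sit on three
bands (1740, 2925, 1160 cm⁻¹) as multipliers spanning roughly ±25 % with
±3 cm⁻¹ shifts on the carbonyl band; variety effects sit on two further
bands (1450, 1050 cm⁻¹) at roughly a third of that strength, nested
within origin.  With peak-effect amplitudes near 0.2 absorbance against
σ = 0.02 noise, the default planted signal-to-noise ratio is about 10.
The ground truth is the set of axis points within ±3σ of a class-affected
band, widened by the largest class shift; *band recovery* of a selection
is the fraction of affected bands containing at least one selected
point — the right granularity for methods that return 5–30 variables
against supports hundreds of points wide.

What the generator does not emulate: Voigt/Mie line shapes, instrument
response, water-vapour interference, scatter effects needing SNV/MSC, and
correlated (pink) noise.  Passing tests therefore certify the pipeline's
mechanics and its behaviour under the planted statistical structure, not
performance on real walnut spectra — which were never deposited.

## Problem sizes

The study-scale configuration (192 × 2751, GA with 10 runs × 1000
evaluations) is used for the selection-recovery checks; classifier sanity
and the task-design orderings run on the 4 cm⁻¹ grid (688 points) of the
same generator, and small seeded matrices serve the algebraic oracles.
These sizes are the package's choices for routine verification; every
knob (axis step, GA budget, fold scheme) is exposed for larger runs.

## Known limitations

* SPA's winner-take-all subset can be unstable between seeds when many
  (start, k) candidates tie within noise; the 10-class task is most
  affected, which mirrors the general experience that discriminating all
  varieties at once is the hardest design.
* The GA trace length defaults to 150 genes; a minimum beyond that range
  would be missed (not observed at the default scale).
* RF models are not JSON-serialisable (sklearn tree internals); persist
  them with joblib if needed.
* The classical 0.5-threshold scoring is recorded but not used for
  accuracy (argmax is); two-class tasks make the two rules coincide
  whenever the threshold rule is decisive.
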