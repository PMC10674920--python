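# Methods

## The classification hierarchy

The package implements a two-level decision hierarchy for highly multi-class
spectral identification. A *global* classifier is trained over all species
of one spectroscopic mode. Its confusion matrix (rows = truth, columns =
prediction, row-normalized to percent) is then mined for *forming species*:
classes whose recall falls below a threshold T. Each forming species
proposes a *dispute group* — itself plus the 1–3 classes that absorb at
least a `mass_fraction` (default 0.20) share of its off-diagonal row mass.
A dedicated *dispute model* is trained per group on the group's classes
only. At inference the global model decides first; only when its answer is
a forming species is the sample re-decided by the corresponding dispute
model. One hybrid model exists per mode; decision-level fusion takes the
majority vote of the per-mode hybrid predictions.

Assumptions baked into this design: (i) confusions are concentrated — a
low-recall species loses most of its mass to a handful of classes, so small
exclusive groups capture it; (ii) the global model's prediction is a good
*router* even when it is wrong, because misrouted samples land on a group
member that the dispute model can still map back; (iii) mode errors are
partially independent, so majority voting helps.

### Exclusivity and group retention

No species may belong to more than one group, in any role. Conflicting
proposals are resolved greedily: every still-open proposal is scored with
the members that remain unclaimed, the largest measured net gain is
committed, and the rest are re-scored. A proposal whose best configuration
has net gain ≤ 0 is dropped. The gain of a configuration is the change,
summed over the group's classes, of recall between the hybrid and the global
decision on held-out data. The greedy search is a documented choice — an
exhaustive search over exclusive assignments is combinatorial and the
procedure's inputs (confusion estimates from a few hundred held-out rows)
do not support distinctions finer than the greedy ordering anyway.

Gains are measured on the same held-out fold whose confusion matrix formed
the groups. The alternative — an inner slice of the training fillets — was
implemented and rejected: because fillet effects are spectrally structured
and constant within a fillet, a model that trained on a fillet is
near-perfect on every row of that fillet, so within-training-fillet gains
are uniformly ≈ 0 and no group would ever be retained. Measuring on the
held-out fold means the reported per-fold deltas are selection-biased
upward (group retention saw the same fold); the cross-seed requirement in
the acceptance suite (improvement in a majority of independent replicates)
is the honest check that the mechanism, not the selection, drives the gain.

### Classifier families

*Global MLP*: dense 512 → dense 128, ReLU, dropout 0.5 on both hidden
layers, L2 weight decay λ = 10⁻⁴ on the hidden kernels, softmax output.
*Dispute CNN*: one unpadded 1-D convolution (64 filters, width 5, stride 4;
output length ⌊(B−5)/4⌋+1, e.g. 14 for the 60-band fluorescence mode) with
SELU, then dense 128 (ELU), dense 128 (Swish), dropout 0.5 after each dense
hidden layer, softmax output over exactly the group's classes.

Both families are trained by Adam (rate 10⁻³, batch 64/32) on class-weighted
categorical cross-entropy with inverse-frequency class weights. The
imbalance-corrected misclassification rate itself is not differentiable, so
it is used where it matters and a surrogate where it does not: training
minimizes the weighted cross-entropy, while *epoch selection* keeps the
epoch minimizing 1 − (class-weighted mean recall) on a fillet-stratified
15% slice of the training rows, with the slice's weighted log loss breaking
the coarse recall ties (without the tie-break, selection can stop on an
undertrained early epoch whose slice recall happens to be perfect).
Training stops after 20 epochs (`patience`) without recall improvement,
capped at 200 epochs by default; the experiment driver and the acceptance
script use 60 epochs/patience 15, which the learning curves show is past
the selection plateau at these problem sizes.

The networks are implemented directly on numpy (dense and strided 1-D
convolution layers with analytic gradients, verified against finite
differences in the test suite; inverted dropout; Adam). All initialization
and shuffling flow from one seeded generator, so training is
bit-reproducible on a fixed BLAS.

Inputs are standardized per band (mean/sd learned from the training split)
inside each classifier; probability outputs sum to 1 within 1e-6 and ties
in the argmax resolve to the lowest class index.

## Cross-validation design

Folds are *fillet-exclusive*: for each species with ≥ k fillets, k distinct
fillets are drawn (seeded) and assigned one per fold as that species' test
fillet; remaining fillets train in every fold. Species with fewer than k
fillets cycle across folds with replacement but never sit on both sides of
one fold; a single-fillet species is tested untrained in exactly one fold
(with a warning). How the original study distributed the extra fillets of
5–12-fillet species across folds is not stated; always-train is this
package's documented choice. Pooling: per-species recalls are computed from
confusion counts pooled over the folds run, not averaged over folds —
matching confusion matrices presented over all test data (whether the
original headline numbers were pooled or fold-averaged is unstated; pooled
is the package's choice).

## Metrics and the repeated-measurement planner

Mean-over-species accuracy is the unweighted mean of per-class recalls
(empty classes are excluded with a warning). Cohen's
κ = (p_o − p_e)/(1 − p_e) uses chance agreement from the row/column
marginals.

The planner computes the fillet-level accuracy of a majority vote over n
independent single measurements of accuracy p as the binomial tail
Σ_{i=(n+1)/2}^n C(n,i) pⁱ(1−p)^{n−i}, implemented via the scipy binomial
survival function and cross-checked against exhaustive 2ⁿ enumeration to
1e-12 in the tests. Note the binomial coefficient: the source formula is
sometimes printed without it, but only the form with C(n,i) reproduces the
anchor values (p = 0.78 gives 0.9256 at n = 5 and 0.9539 at n = 7, hence
"7 measurements reach 95%" — without the coefficient n = 7 would give
0.068). The default threshold T = 0.78 is exactly the smallest
single-measurement accuracy from which 7 measurements reach a 95% target.

## Hypercube preprocessing

Reflectance cubes are flat-field calibrated, (I_sample − I_dark)/(I_white −
I_dark); fluorescence cubes are dark-subtracted and divided by a constant
6000 (≈ the data-wide maximum count). The fillet mask thresholds each
pixel's broadband mean intensity at the midpoint between robust background
and fillet levels (whether the original masks were thresholded or manual is
unstated; the threshold rule is a configurable stand-in). Masked pixels are
grouped into 10×10 voxels on a fixed 0-based half-open grid. The outlier
statistic is scalar: each pixel's broadband mean intensity, with μ and σ
taken over all fillet pixels of the cube — a per-band rule at 287 bands
would flag nearly every pixel somewhere. A pixel is an outlier outside
[μ−2σ, μ+2σ]; a voxel is excluded iff its outliers exceed 10% of its masked
pixels, *strictly* ("more than 10%": 10 of 100 retained, 11 excluded).
Edge voxels with fewer than 50 masked pixels are dropped so voxel means
stay comparable. Valid voxels contribute the mean spectrum of their masked
pixels. The whole stage is deterministic and is checked against an
exhaustive per-voxel re-derivation on cubes up to 50×50.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* that the method's claims depend
on, not fish biochemistry:

- **Confusability clusters.** Species means per mode are built from a
  smooth positive baseline plus jointly orthonormalized smooth random
  directions (sums of 3–6 Gaussian bumps), so two species of one cluster
  are exactly d_w·√2 apart and species of different clusters ≈ d_b·√2.
  The d_w/d_b ordering is therefore exact by construction.
- **Fillet effects.** Each (fillet, mode) draws a smooth additive offset —
  a random low-order Legendre polynomial with per-band variance σ_f² — not
  white noise. Structured offsets are what make leave-fillet-out validation
  genuinely harder than row-level splits.
- **Measurement noise.** iid N(0, σ_e²) per band, emulating voxel-mean
  residual noise.
- **Hypercubes.** An elliptical fillet on a dark background in raw counts
  (dark floor 100, gain 4000), with known white/dark references and
  outliers injected at known positions by intensity inflation, recorded in
  a truth mask.

Defaults are the study conditions: 43 species, clusters {2,2,3,3,4,4} plus
25 singletons (mirroring observed dispute-group sizes of 2–4), 4 fillets
per species, 10 voxels per fillet per mode, d_b = 1.0, σ_f = 0.04,
σ_e = 0.05, and d_w = 0.07 for the confusable preset — chosen once so that
the preset satisfies its definition: global mean-over-species accuracy
lands in the 70–80% band with clustered species below T while singletons
stay near 100%. The separable preset raises d_w to 1.0 (≫ σ_e).
Within- vs between-fillet variance components for real fillets are not
reported anywhere; these defaults are free parameters of the simulation,
documented, and not claims about fish.

What passing tests on this data do **not** show: robustness to instrument
drift between acquisition sessions, scattering/geometry artifacts,
non-Gaussian tissue heterogeneity, or class-dependent noise — all present
in real fillet data and all outside the generator. Results here validate
the machinery (formation, exclusivity, routing, fusion, planning), not
field performance.

## Numerical and design choices

- Tie-breaks: argmax ties → lowest class index; fusion vote ties → mode
  priority Fluor > VNIR > SWIR by default (the descending order of observed
  single-mode accuracies), or highest posterior confidence as an
  alternative policy. Three-way-tie handling is unspecified in the source
  method; both policies are provided.
- Candidate-member cutoff (`mass_fraction` 0.20) and cap (`max_members` 3)
  are not specified by the source method; the defaults produce group sizes
  of 2–4 and both are configurable. If no absorber reaches the cutoff, the
  single largest absorber is used.
- The dispute CNN's layer wiring is given ambiguously in the source prose
  (dense hidden layers vs "convolutional layers in each hidden layer"); the
  reading consistent with the layer-by-layer enumeration — one conv input
  layer, two dense hidden layers — is implemented.
- Degenerate inputs: single-class training sets, missing group classes,
  empty masks, zero calibration denominators, even planner n, and p ≤ 0.5
  planner requests all raise typed errors naming the offending entity;
  voxelization that retains nothing warns and returns an empty grid.
- Problem sizes in the shipped experiment driver defaults, acceptance
  script and test suite (single CV fold, 60-epoch budgets, 10 voxels per
  fillet) are the package's chosen desk-scale study conditions; all are
  parameters, and k = 4 full cross-validation is one argument away.

## Known limitations

- Greedy, not exhaustive, exclusivity resolution (see above).
- Per-fold dispute-group deltas are selection-biased upward; only
  cross-seed replication is unbiased evidence of improvement.
- The numpy trainer is single-threaded via BLAS and intended for
  desk-scale data (thousands of rows, hundreds of bands); it has no GPU
  path.
- Fusion is decision-level only; probability-level fusion is out of scope.
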