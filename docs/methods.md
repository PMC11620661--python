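# Methods

This note documents the models, conventions and numerical choices
behind `vwmgeom`, and what the synthetic validation does and does not
establish about real data.

## Experimental structure emulated

Both emulated experiments present 16 trial conditions once per run.
Experiment 1: one memory target (4 object types) retained over a 10-s
delay filled either with a sequence of distractor exemplars (3
distractor types per target) or a blank screen — 12 target×distractor
conditions plus 4 no-distractor conditions; trials are 15 s, runs
5 min 4 s (TR 0.8 s), with an 8-s blank at both run ends and 15
inter-trial blanks (three 8 s, twelve 2 s) placed at random. Trial
onsets are jittered relative to the TR grid by that placement and are
rounded to the nearest TR. Experiment 2: two sequentially presented
targets — all 12 ordered pairs of 4 objects plus 4 single-target
conditions; trials are 15.2 s and runs 5 min 12 s. The protocol
leaves the Experiment 2 blank budget under-determined (15.2-s trials
with the Experiment 1 blanks do not sum to the printed run length);
we use three 8-s plus twelve 2.4-s blanks, which reproduces the run
length exactly and puts every onset on the TR grid, as stated for
that experiment.

Runs are organized into 4 splits (2 sessions × odd/even). Each split
of 7 runs yields 7 leave-one-run-out 6-run GLM combinations (6-run
splits: the six 5-run combinations plus the full set), so every
condition has 4 × 7 = 28 pattern estimates, independent across splits
but correlated within a split.

## Synthetic generative model

Condition means live in a vertex space of dimension `n_vertices`
(default 200, a mid-sized ROI). The 4 objects sit at the vertices of
a regular tetrahedron spanning a 3-D *target subspace*, scaled so
that any two objects' means are `2 · target_amplitude` apart — all 6
object pairs are equally separable. Each context (distractor
identity, distractor absence, or partner-target identity) has its own
copy of the target subspace built from an equicorrelated basis

    f_mk = √(cos θ) · g_m + √(1 − cos θ) · e_mk,

with `g_m` and all `e_mk` orthonormal. Corresponding basis vectors of
any two contexts then subtend exactly θ, so the planted angle between
same-pair target-difference vectors is exact (float-exact at θ = 0
and 90, ≤ 1e-13° elsewhere; verified to 1e-9° in tests). Each
distractor/partner context adds its own orthogonal offset axis scaled
by `context_amplitude`, making context identity itself decodable.
Experiment 2 ordered pairs are the sum of the two targets' codes
(each in the context of its partner) plus an order-tagging component
(`order_amplitude · (z_first − z_second)` with orthonormal `z_t`).
Because both pair members' codes are context-dependent, pair-level
difference angles are exact only at θ = 0 (≈ 82° at a planted 90°);
Experiment 1 is exact at every θ and is what the calibration studies
use.

Pattern estimates are `mean + shared + unique` with `shared ~
N(0, (ρ·σ)²)` drawn once per (condition, split) — emulating the
shared-run dependence of the 7 GLM estimates of a split — and
`unique ~ N(0, σ²)` i.i.d.; splits are independent. Defaults: σ = 1,
ρ = 0.5. Optional run time series place each trial's 30-TR response
profile (rise by ~4.8 s, sustained plateau, return to baseline by
~19 s; no hemodynamic convolution, matching the model-free FIR
approach) at its onset, times the condition mean, plus i.i.d. TR
noise.

**Calibration.** The study condition for the ratio analyses is
within-decoding ≈ .75. With the defaults above, a grid search over
the amplitude (on seeds independent of those used anywhere else)
gave `target_amplitude = 1.9` (within ≈ .75 at 21 train / 7 test,
200 vertices); `context_amplitude = 1.9` keeps context and target
signals on the same scale, and `order_amplitude = 0.95` is half of
it. These are frozen defaults, not per-analysis dials. Note that the
shared split component materially lowers attainable accuracy (the 7
test estimates of a split rise and fall together), which is the
realistic regime.

What the generator does **not** emulate: vertex-to-vertex noise
correlations, heteroscedasticity, physiological/temporal noise
structure, ROI-size variation, behavioral lapses, or any hemodynamic
shape. Passing tests therefore show that the pipeline recovers known
geometry under idealized noise, not that real cortical data have any
particular geometry.

## Decoding conventions

- z-normalization is per pattern across vertices, sample-SD (n − 1)
  convention, applied before training and testing.
- Classifier: `sklearn.svm.SVC(kernel="linear", C=1)` (libsvm). The
  analyses depend on linearity and determinism, not on the margin
  solver; C is configurable.
- Training and test splits never overlap; cross tasks are enumerated
  as directed pairs and averaged at the analysis level, making the
  cross accuracy symmetric in the two contexts.
- Experiment 2 pools the two presentation orders of a pair as extra
  exemplars of the same class (42 train / 14 test per class).
- All 7 test estimates of a split are scored even though they are not
  mutually independent, exactly as the estimation scheme implies.
- Probit transform: `Φ⁻¹(clip(acc, ε, 1−ε))` with
  `ε = 1/(2·n_estimates)` (n_estimates = 28 for the standard scheme) —
  a standard continuity correction keeping ceiling accuracies finite.

## FIR GLM

One indicator regressor per (condition, TR-lag) for lags 0..29
(0–24 s), built per run and concatenated per run combination with
per-run intercepts; OLS per vertex. Rank deficiency raises an error
naming the number of collinear columns — with one trial per condition
per run, designs need roughly 4+ runs per combination to be
identifiable, which is why the protocol combines 5–6 runs. Windows
are half-open `[start, end)` in seconds, mapped to lags whose start
times fall inside (delay, Experiment 1: 9.6–12 s → TRs 12–14; delay,
Experiment 2: 10.4–12.8 s → TRs 13–15; encoding: 4.8–8 s → TRs 6–9).
Trailing lags of trials that extend past the run end are clipped with
a warning. No prewhitening, drift or nuisance regressors (detrending
belongs to preprocessing, which is out of scope).

## Geometry

RDM entries default to **above-chance accuracy** (accuracy − .5).
The chance baseline is not a distance: retaining it (entry
`"accuracy"`, also available) injects a large spurious third MDS
dimension — a planted 0° geometry is read out as ≈ 53° with raw
accuracies versus ≈ 1–4° with the baseline removed. A `"probit"`
entry convention is also provided. Entries are left unclipped so that
group averaging stays unbiased; the embedding floors dissimilarities
at zero and truncates negative Gram eigenvalues (their mass is
reported). Classical (Torgerson) MDS is used for determinism; with 4
points, 3 dimensions capture the configuration fully. Line angles use
`arctan2` of the orthogonal rejection (numerically exact for parallel
vectors, unlike `arccos` of a normalized dot product) and are folded
to [0, 90]° — lines, not vectors, carry the parallelism question, and
3-D angles have no meaningful sign.

Per-participant angles are averaged over quartets (then, in larger
designs, over ROIs); group angles average the N−1 remaining
participants' RDMs entrywise per quartet before embedding, once per
left-out participant (N jackknife estimates, summarized by their mean
and SE).

**Known limitation — mid-range angle compression.** Decoding accuracy
is a saturating, finite-sample-limited function of pattern distance,
so RDM "distances" compress real distance differences. At the
calibrated signal level the jackknife group angle is strictly
monotone in the planted θ and recovers the endpoints (θ = 0 → ≈ 2–4°,
θ = 90 → ≈ 75–86° across seed sets), but intermediate angles are
biased low (planted 30° → ≈ 5–10°, 60° → ≈ 10–24°). Probit entries
reduce, but do not remove, this bias. Interpret intermediate absolute
angles cautiously; ordinal comparisons and the parallel-vs-orthogonal
contrast are the robust readouts.

## Statistics

- t tests: one-sample against chance (one-tailed, since only
  above-chance decoding is meaningful) and paired comparisons; exact
  zero-difference samples return t = 0 rather than an error.
- Benjamini–Hochberg step-up adjustment with enforced monotonicity,
  applied within user-defined families (tests of the same type within
  an ROI or sector); verified against the brute-force step-up
  definition on all permutations of up to 6 p values.
- Two-way repeated-measures ANOVA on complete balanced tables, each
  effect tested against its subject × effect interaction; no
  sphericity correction by default (none is reported in the emulated
  analyses). Cross-checked against pingouin and a sums-of-squares
  oracle.
- Paired-t power: smallest n whose noncentral-t power (noncentrality
  `dz·√n`, df n − 1) reaches the target; oracle values dz = 1 →
  n = 8 (one-tailed) and dz = 0.5 → n = 34 (two-tailed) at power .80,
  α = .05.
- Cross-decoding ratio guard: δ = .02 above chance; below it the
  ratio is flagged invalid instead of exploding.

## Signal-strength simulations

Signal strength `s` is the Mahalanobis distance between class means
under the first class's unit isotropic noise — chosen because it
gives the ideal observer the closed form `Φ(s/2)`, whose probit is
exactly `s/2` (slope ½, R² = 1), an analytic anchor for the
linearization claim. The default battery is 10 cases: n_vertices ∈
{20, 200} × n_train ∈ {10, 20, 40}, plus 4 unequal-variance cases
(class-B SD 1.5 or 2 at both vertex counts) whose signal grids
stretch proportionally so every case spans floor to ceiling; grids of
17 points, 100 repetitions, 100 test patterns per class per rep. In
every case the full-range linear fit is better on probit than on raw
accuracy, while both are comparably linear over the mid-range — the
transform matters at the extremes, except exactly at chance where the
probit is undefined without clipping.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (sub-seeds derived
via `numpy.random.SeedSequence`); identical configs give bit-identical
outputs and manifest checksums. The calibration studies use 100
datasets per planted angle for the ratio analyses, 200 label-permuted
datasets for the chance calibration (plus 500 groups of 8 for type-I
calibration of the t test), and 12 synthetic participants × 2
quartets for the angle-recovery study — sizes chosen so Monte-Carlo
error is several times smaller than the effect bands being checked.
The pattern route (sampling estimates directly) is used for these
studies; the GLM route is validated separately by exact noiseless
recovery and is equivalent up to estimation noise.
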