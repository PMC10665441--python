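# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions implemented in `dynica`, and what the synthetic benchmark does
and does not establish about real data.

## 1. Data model and preprocessing

A promoter-reporter experiment is described by an `ExperimentDesign`: an
ordered list of heavy metals, one 4-h (240 min) induction window per metal,
a 10-min raw imaging grid, and a 40-min analysis grid — six selected points
per induction window (`start + j·40`, j = 1..6; the reference at the window
start is not a column, so six metals give exactly 36 induction columns) and
twenty per recovery period (`end + j·40`, referenced to the window end).
The default layout separates consecutive windows by an 840-min recovery span
so the twenty recovery samples (800 min) always fit.

Preprocessing is a fixed chain:

1. **Background correction** `u(t) = (raw(t) − bg(t)) / bg(t)` — the signal's
   amplification over the local background; non-positive backgrounds are an
   error naming the promoter and sample.
2. **Median filter**, running median with kernel 11 on the 10-min grid
   (`scipy.signal.medfilt`, zero-padded edges).  At 10-min sampling this is a
   110-min window — a strong filter that removes isolated impulse artifacts
   but also interacts with genuine temporal structure (see §2).
3. **Control normalization** `n(t) = (u(t) − c̄(t)) / c̄(t)` against the mean
   of the identically processed promoterless strains.
4. **Windowed log2 fold change** `log2(n(t_j) / n(t_ref))` per metal.

Selected times must exist exactly on the grid (the 10-min grid contains all
40-min offsets); there is no interpolation.  Normalized values can be
non-positive when a promoter's signal falls below the control; rows whose
required values include a non-positive entry get a small additive offset
(10⁻³ × the global median of positive normalized values) on numerator and
denominator, and are dropped with a logged warning if any value remains
non-positive.  The offset is applied only to such rows — strictly positive
rows use the exact ratio, which keeps the noise-free round trip against the
generator exact.  Promoters with any dropped window are removed from the
whole matrix (ICA needs complete rows).  The chain is invariant to a common
positive rescaling of all fluorescence values.

The recovery-phase matrix has `n_metals × 20` columns (120 for six metals).

## 2. Synthetic data generator

The generator is first-class, tested code: it plants a known decomposition
and emits either the fold-change matrix directly or a full raw-fluorescence
experiment whose preprocessing round-trips to the planted values.

**Planted weights.** Each of `k` components receives a member support drawn
as a Binomial(n, `weight_sparsity`)-sized sample of promoters (disjoint
across components by default; configurable overlap).  Member weights are
`weight_scale · (1 + jitter)` with 5% Gaussian jitter (clipped), optionally
sign-balanced via `weight_sign_frac`; off-member weights are
N(0, (`weight_scale`/20)²), clipped to ±`weight_scale`/4 so the member set is
exactly the set of weights with |w| ≥ `weight_scale`/2.  The near-normal
off-member bulk is what the K² thresholding is tested against.

**Planted activities.** One shape template per component, max-normalized to 1
(amplitude lives in the weights, matching ICA's scale convention), placed in
the component's assigned metal window: steady (linear ramp 1/n..1), fast
(geometric decay from 1, ratio 0.5), intermediate (unimodal peak at
⌈n/2⌉+1, linear flanks), partial-steady (ramp dropping to 0.1 at the last
point), late (zeros for the first half, then a ramp).  After the window, the
activity decays linearly to zero over 12 recovery samples.

**Raw fluorescence.** For promoter *p* with planted log2 fold-change curve
`f_p(t) = Σ_k m_pk · g_k(t)`,

```
raw_p(t) = background + baseline · c(t) · h(f_p(t)),
h(f) = ((ρ−1)·2^f + 1)/ρ,   ρ = baseline_level / control_level,
```

and promoterless strains emit `background + control_level · c(t)`.  The map
`h` is the monotone expression curve for which subtract-and-divide control
normalization yields exactly `(ρ−1)·2^f`, so the recovered fold change equals
the planted one by construction.  (The naive choice `h(f)=2^f` cannot be
inverted exactly by subtract-and-divide normalization: it leaves a
`−1/ρ`-order bias.)

**Median-filter transparency.** A kernel-11 running median at 10-min spacing
spans ±50 min around each 40-min-spaced sample, so a strict activity peak at
a sampled point is always clipped under linear interpolation — no continuous
interpolant can make the filter exact there.  The generator therefore fills
the grid between 40-min knots with a staircase `(v_a, v_a, v_b)` and widens
the plateau over the gap left of each strict local maximum.  One can verify
(the tests do, for all five shapes and both phases) that the window median at
every sampled point then equals the knot value exactly, and that a single
impulse in a staircase region leaves the median unchanged.  Consequences:
the round trip is exact (≈1e-15) at zero noise, and exactness requires one
component per metal window — two components sharing a window mix shapes
inside the filter window and break the order-statistics argument.  The
default configuration plants one component per metal.

**Noise model.** `noise_sd` is additive noise on each component's log2
activity at the 40-min knots — the pathway activity itself fluctuates, and
the fluctuation is shared by every promoter reporting the component (the
realized curve is a noisy staircase, so the filter still acts identically on
all reporters and the matrix stays essentially rank-k).  `measurement_sd`
(default 0.02) is independent per-promoter, per-sample noise on the log2
signal.  Impulse artifacts of height 5× baseline occur with probability
`spike_prob` per sample.  `generate_fold_change` instead adds i.i.d.
per-entry Gaussian noise to `M·A` — the simpler matrix-level benchmark.
Neither noise scale is an instrument estimate; the source data ship no
quantitative noise model, so the defaults (0.05 activity, 0.02 measurement,
1% spikes) are chosen as plausible and are stated here rather than fitted.

With noise in the loop the recovered fold change deviates from the template
by the realized activity fluctuation; the round-trip guarantee becomes
distributional (almost all sampled points within 3·`noise_sd`), not a
max-norm bound.

## 3. Robust ensemble ICA

Columns of X are mean-centered (no variance scaling — fold changes share
units, and scaling would distort weight comparability).  The dimension k is
the smallest number of principal components reaching 99% cumulative
explained variance.  FastICA (parallel extraction, log-cosh contrast,
unit-variance whitening, tolerance 1e-6) is run `n_runs = 100` times with
derived seeds; sources live in gene space (M columns, unit L2 norm, the
largest-magnitude entry oriented positive, ties broken by the lower row
index) and mixing in condition space (A rows, carrying the scale).

A run is treated as failed — retried once with a fresh seed, then skipped
with a log entry — only if the solver errors or returns non-finite output.
Reaching the iteration cap is *not* failure: with a 99%-variance dimension
the weakly non-Gaussian directions routinely exhaust any cap, and the
ensemble clustering, not per-run convergence, is the stabilizing mechanism.

Pooled components are clustered with DBSCAN under `d(u,v) = 1 − |pearson
r(u,v)|`, radius 0.1, minimum cluster size `ceil(min_frac · n_runs)` (the
"half of the data" rule is read as half of the runs — one member per run);
noise points are discarded.  Each cluster's robust component is the
sign-aligned mean of its members, renormalized to unit L2 with the norm
pushed into the A centroid, preserving the cluster-mean reconstruction.
The whole ensemble-plus-clustering computation is repeated `n_repeats = 100`
times with fresh base seeds; a candidate is retained only if every repeat
contains a centroid with |r| > 1 − 0.1 = 0.9 to it, matched greedily by
descending |r| (one-to-one).

`IcaConfig.fast()` is the desk-scale mode: 10 runs × 10 repeats, tolerance
1e-5, iteration cap 1000.  The looser per-run settings are deliberate — the
cross-run clustering supplies the robustness — and the planted-module
benchmark passes at the same rates as with the full-scale settings in a
fraction of the time.

Reconstruction is reported on the centered matrix (`X_c ≈ M·A`); the removed
column means are stored on the decomposition (`reconstruction()` adds them
back).  With all-positive planted memberships X carries a rank-one
column-mean structure of relative Frobenius weight ≈ √sparsity that centered
ICA cannot represent, which is why the reconstruction bound is stated on the
centered matrix.

A property worth knowing: on a *fixed* finite sample of pure Gaussian noise,
FastICA restarts reproduce the sample's empirical-kurtosis directions, so the
ensemble machinery can retain components that reflect that realization rather
than any planted structure.  Run-to-run reproducibility on one matrix is
therefore evidence of structure *in that matrix*, not of biological signal;
only planted-truth benchmarks (or replication across datasets) separate the
two.

## 4. Characterization

**Membership (K² threshold).**  The D'Agostino K² omnibus statistic
(transformed skewness Z² + transformed kurtosis Z², implemented from the
standard small-sample formulas and checked against scipy's omnibus test to
1e-8) measures how far a weight column is from normal.  Promoters are
removed one at a time in descending |weight|, recomputing K² on the
remainder, until K² < 800; the membership boundary is the |weight| of the
last-removed promoter (+∞, empty membership, if the column starts below the
cutoff), and only positively weighted removed promoters count as members.
The statistic needs ≥ 20 finite values; fewer remaining before the cutoff is
reached flags a degenerate component.  K² is scale-invariant, so membership
is invariant to positive rescaling of the column.  Note the fixed cutoff of
800 is calibrated for library-scale columns (~1800 promoters); on matrices
with only a few hundred rows the initial K² of a genuine module may already
sit below it, yielding empty memberships.

**Single-promoter discard.**  A component is flagged (retained in outputs,
`discarded=true`) when its member set is a singleton or the largest squared
weight exceeds 70% of the column's total squared weight; the share is
configurable since the source analysis states no quantitative rule.

**Primary metal.**  The metal whose induction window has the highest
aggregate activity (sum of the A-row entries in the window); exact ties go
to the earlier metal in the design order.

**Temporal shape.**  For the 6-point induction profile, negative activities
are clipped to zero for the center-of-mass weighting (CM locates activation
mass; repression should not shift it — an interpretation, recorded as such):
`cm = Σ i·w_i / Σ w_i` (1-based), `hp` = 1-based argmax (earliest on ties).
The printed rules overlap, so they are applied most-specific first:
Fast (cm ≤ 4, hp ≤ 3) → Intermediate (cm ≤ 4, hp ≤ 4) → Steady (cm ≤ 5,
hp ≥ 4) → Other.  Every finite profile receives exactly one label; an
all-nonpositive profile is Other with cm reported missing.  The
partial-steady template classifies as Steady and the late template as Other
under these rules — the rules produce only the three printed labels, and
Other profiles are reported with their cm/hp for case-by-case inspection.
Recovery-phase profiles (20 points) get cm/hp but no label (the printed
thresholds are 6-point specific).

**Category shift.**  Given a user-supplied promoter→category table
(stress/damage, transcription/translation/synthesis, other — the package
consumes such annotations, it does not create them), member promoters of the
non-discarded iModulons are counted per category per phase; unannotated
members count as "other", and fractions are reported as missing for empty
member sets.

## 5. The synthetic benchmark: what it shows and what it does not

The acceptance surface (`scripts/acceptance.py`, `tests/test_acceptance.py`)
runs at deliberately desk-scale sizes: 30–60 promoters for geometry and
round-trip checks, 300 promoters × 36 conditions × 20 seeds for ICA
recovery, 50 randomized 1805-promoter columns for the threshold oracle.
The ICA recovery benchmark plants five modules (fast, intermediate, two
steady, late; 5% membership) at a member-weight to activity-noise ratio of
5 with `spike_prob = 0` — impulse robustness is the median filter's concern
and is tested separately, and at a 1% rate spikes occasionally synthesize
real two-promoter artifact components that confound the count of retained
components without bearing on ICA recovery.

Passing these tests shows the pipeline is a faithful, self-consistent
implementation: it inverts its own generative model exactly in the noise-free
limit, recovers planted structure at the stated noise, and matches
independent oracles for its statistics.  It does *not* show that real
promoter-reporter data satisfy the generator's assumptions — in particular
real data have growth and maturation dynamics, spatially correlated
backgrounds, plasmid copy-number effects, promoters reporting several
regulons at once, and activity shapes that are not staircases.  The
classification rules are tailored to the 6-point window and the shapes
observed in the source study; other designs need re-derived thresholds.

## 6. Numerical conventions and degenerate inputs

- Written matrices use `%.17g` floats and are re-read with round-trip
  parsing, so rerunning any stage from its written artifacts is bit-identical
  to running it in-line; every artifact carries version, seed and input
  digests in `#` header comments.
- All randomness derives from a single seed (config seeds plus fixed salts,
  kept below 2³¹); identical seeds give bit-identical outputs.
- Zero-variance matrices abort at dimension selection with a stage-named
  error; an empty robust set is a valid decomposition (k=0), not an error.
- Ties: argmax-based rules (sign orientation, highest peak, primary metal)
  resolve ties to the lowest index / earliest design entry.
- The center of mass is clipped into [1, n] to absorb float roundoff at the
  boundaries.
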