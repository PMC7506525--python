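# Methods

`envnet` implements a resting-state MEG oscillatory-connectivity
analysis operating on atlas-node timecourses: band-limited signals are
turned into leakage-corrected amplitude-envelope connectomes, compared
between two groups with permutation- and resampling-based statistics,
and summarized as per-subject weighted graphs whose nodal metrics feed
a cross-validated linear classifier of group status.  A synthetic
cohort generator with known ground truth makes every stage testable
end to end.  This note records the model, the parameters that matter,
and the design choices made where the method leaves room.

## Connectivity model

Amplitude–amplitude coupling between two nodes is the Pearson
correlation of the slow amplitude envelopes of their band-limited
oscillations.  The per-subject, per-band chain is fixed:

1. **Band-pass filter.** 4th-order Butterworth, applied
   forward–backward (`sosfiltfilt`) for zero phase.  The canonical
   bands are delta 2–4, theta 4–8, alpha 8–13, beta 13–30, low gamma
   40–60 and high gamma 60–90 Hz.  The padding length scales with the
   filter's low-edge time constant (6/f_lo seconds) so slow-band
   transients decay inside the pad rather than contaminating the data.
2. **Symmetric multivariate orthogonalization.**  Source-reconstructed
   signals mix linearly at zero lag (field spread), inflating every
   connectivity estimate.  We replace the node signals X (time × node)
   with the matrix of mutually orthogonal columns closest to X in the
   Frobenius sense, Y = O·diag(d) with OᵀO = I, found by alternating
   two exact partial minimizations: the orthonormal polar factor of
   X·diag(d) (via SVD), and the per-column projections d_k = x_k·o_k.
   Convergence: relative residual change below 1e-9, at most 100
   iterations (an error reports the residual if exceeded);
   initialization d = 1, which makes the first O-step the polar
   decomposition of X.  Rank-deficient input is rejected with the
   offending columns named (identified by pivoted QR).  The treatment
   is symmetric in the nodes, unlike pairwise regression approaches.
3. **Hilbert envelope.** Per-column magnitude of the analytic signal.
4. **Despike, downsample, trim.** Running median (default window
   0.25 s, forced to an odd sample count) suppresses impulsive
   artifacts; non-overlapping 1-s window means reduce the envelope to
   1 sample/s; 2 s are trimmed from each end to discard filter and
   Hilbert edge effects.  The window, trim, and filter order are
   package choices — the procedure itself fixes only "median filter,
   1 Hz, trimmed".
5. **Correlation and Fisher transform.** Pearson correlation of the
   1 Hz envelopes, then z = atanh(r).  Correlations of magnitude 1
   (degenerate inputs) are clipped to 1 − 1e-12 with a warning rather
   than producing infinities.
6. **Per-subject normalization.** Each subject's map is z-scored
   across its upper-triangle edges (population SD), absorbing global
   differences in connectivity level such as data quality.  Note a
   side effect quantified below: group effects concentrated at some
   edges bleed, with opposite sign, into all other edges of the
   normalized map.
7. **Combined-frequency map.** Per edge, the Euclidean norm
   √(Σ_b z_b²) of the band-wise normalized values ("vector-sum"); a
   plain-sum alternative is available.  The norm is nonnegative, so it
   folds the sign of negative z-values: edges in the weak half of a
   subject's map cannot be ordered through the combined map.  Group
   statistics on synthetic data are therefore validated on per-band
   normalized maps, where monotonicity is exact.

Edge vectors use one convention everywhere: upper triangle, 0-based
node indices, i < j, lexicographic order (n(n−1)/2 = 4005 edges for 90
nodes).

## Synthetic cohorts

The generator emulates the structure of a two-group resting-state MEG
study — 42 subjects per group, 90 cortical nodes, six bands, 250 s at
600 Hz — at configurable size.  Signals are multiplicative:
a band-passed white-noise carrier times a strictly positive slow
envelope, exp(σ·g), where g is a correlated Gaussian process low-pass
filtered to the envelope bandwidth (default 0.5 Hz, matching the 1 Hz
envelope sampling) and σ = 0.5 sets modulation depth.  The latent
correlation of g equals the target envelope-correlation matrix;
measured envelope correlations attenuate (carrier amplitude noise,
filtering, 1-s averaging — about a factor 0.7 at the defaults), so
tests assert ordering and monotonicity, never equality to the target.
The latent process is synthesized at 20× the envelope bandwidth and
interpolated to the signal rate; a 4th-order low-pass at 0.5 Hz
applied directly at 600 Hz would be numerically unstable.

Target matrices: unaffected edges carry a *baseline profile*
baseline_corr·(1 + baseline_spread·u), u uniform on [−1, 1], drawn
once per cohort and shared by every subject.  The profile is what
gives group-level rank maps their meaning — real connectomes have a
stable strong-edge backbone; with a flat baseline all edges are
exchangeable and rank thresholding is degenerate.  Affected edges
(uniformly sampled without replacement, ground truth returned to the
caller) are reduced by the fractional effect_delta in the case group
only.  Matrices are repaired to positive semidefiniteness by
eigenvalue clipping and unit-diagonal rescaling, since user-specified
edge patterns need not be jointly consistent.

Leakage: each subject's signals are mixed by I + λR with R a fixed
random symmetric zero-diagonal matrix (unit-scale entries, one R per
subject across bands — leakage reflects geometry, not frequency), and
columns rescaled to their input variance.  Defaults λ = 0.1 and
effect_delta = 0.5 were calibrated once so that, at the validation
scale (20 nodes, alpha band, 150 s at 120 Hz, 42 per group, 30
affected edges), the measured edge-level effect size is Cohen's
d ≈ −1.  Heavier mixing (λ = 0.2 with unit-scale entries) genuinely
blends the sources: orthogonalization can then no longer recover the
effect, which collapses to d ≈ −0.3 — a real property of the
correction, not an implementation artifact.

Covariates: ages are normal (cases 38.5 ± 12.5 years, controls
33.3 ± 9.6, truncated at 18), gender is balanced, and intracranial
volume is normal in 1-mm-voxel units with a small case deficit
(1.45·10⁶ vs 1.50·10⁶, SD 1.2·10⁵) so the confound-regression path is
exercised.  One independent signal realization per band; no cross-band
coupling (bands are treated separately until the vector-sum stage).

What the generator does *not* emulate: sensor-level physics, forward
models, head motion, non-linear artifacts, spatially structured
(distance-dependent) leakage, autocorrelated covariate effects on
connectivity.  Passing tests demonstrate the statistical machinery is
correct and calibrated under the stated generative model, not that the
pipeline's assumptions hold in real MEG data.

## Group statistics

**Valid-edge selection.** Each subject's edges are rank-transformed
(average ranks on ties, normalized by edge count); rank maps are
averaged per group; an edge is valid for a group when its mean
normalized rank exceeds 0.8 (top 20%); the final mask is the union of
the two groups' selections.  Ranks make the mask invariant to any
strictly monotone per-subject transformation.  At desk scale (few
subjects, short recordings) the mean rank regresses toward 0.5 and the
consensus can be legitimately empty; the pipeline command then falls
back to the full edge set with a logged warning.

**Welch tests and omnibus correction.** Per valid edge, Welch's
unequal-variance t with Welch–Satterthwaite df, two-sided p; positive
t means case > control.  Family-wise error is controlled by the
maximal statistic: group labels are permuted (preserving group sizes —
sign-flipping is a paired-design device; label permutation is the
two-sample analog), the max over valid edges of |t| is recorded per
permutation, and the threshold is the empirical 95th percentile of
that null distribution.  Omnibus-significant edges are by construction
a subset of uncorrected-significant ones.

**Split-half sign consistency.** Per iteration, ⌊n_g/2⌋ subjects per
group are drawn without replacement and the case−control mean
difference's sign is tabulated per edge; an edge is robust when one
sign occurs in ≥ 95% of iterations (zero differences count against
both signs).  A structural property worth knowing: the iterations
subsample one fixed cohort, so their signs are strongly correlated —
conditional on the data, the subsampled difference is centered on the
observed difference with sd equal to the *between-cohort* sampling sd
of that difference.  A null edge's consistency is therefore Φ(|z|)
with z standard normal (uniform-ish on [0.5, 1)), and the expected
null robust rate at the 95% level is 2·Φ(−1.645) ≈ 10%, not ~0, with
per-subject-normalization bleed adding a few points on synthetic
cohorts with many affected edges.  The criterion measures
*replicability of direction in this cohort*, not family-wise error;
treat robust-edge counts accordingly.

**Covariate regression.** Ordinary least squares of each valid edge on
[intercept, group, age, gender, ICV] within each random half-cohort;
the group-slope sign is tabulated over (default) 1000 halves with the
same 95% criterion.  Gender is coded 0/1 and ICV enters in raw voxel
units — slopes are scale-dependent but the tabulated signs are not.
Collinear designs are rejected with the offending columns named; the
half-cohort must contain at least 6 subjects to identify 5 parameters.

**Post-hoc power.** Classical equal-n two-sample power: noncentrality
d·√(n/2), pooled df 2n−2, two-sided central-t critical value,
noncentral-t tail probability.  At n = 42 this gives 95% power for
d = 0.8 and 62% for d = 0.5 (the pooled-df convention is what
reproduces those round figures; Welch df would differ at the third
decimal).

## Graphs and nodal metrics

Each subject's map is thresholded to its ⌈0.2·E⌉ strongest edges (ties
broken by lexicographic edge index; fraction 1 gives the unthresholded
variant used as a robustness check).  Connectivity weight w is
proximity; path computations use distances 1/w.  Nonpositive retained
weights — possible only in unthresholded mode — stay in the graph for
degree counting but are excluded from path metrics, with a logged
warning.

Per node: **degree** (count of retained incident edges — the one
binary metric), **betweenness** (fraction of shortest paths through
the node, normalized by (n−1)(n−2)/2, endpoints excluded),
**eccentricity** (max shortest-path distance within the node's
component; isolated nodes get 0), **nodal global efficiency** (mean
1/d to all other nodes; unreachable pairs contribute 0), **local
efficiency** (mean 1/d within the neighbor-induced subgraph, same
1/w distances), and **clustering** (Onnela geometric-mean form on
weights normalized by the graph maximum; raw connectivity weights,
not inverses, since clustering is a triangle-density notion).  Nodes
with fewer than two neighbors get clustering and local efficiency 0.
Shortest paths are Dijkstra (`scipy.sparse.csgraph`); betweenness and
clustering use networkx; all six metrics are verified against
exhaustive path- and triplet-enumeration oracles to 1e-10 on small
graphs.  Scaling all weights by c > 0 leaves degree, betweenness and
clustering unchanged, scales eccentricity by 1/c and efficiencies
by c.

## Classification

A linear SVM (fixed C = 1; the metrics have heterogeneous scales, so
features are z-scored using training-fold statistics only) is
evaluated with 100 repetitions of stratified 5-fold cross-validation:
fresh fold assignment per repetition, accuracy / sensitivity /
specificity computed per repetition from the pooled held-out
predictions and then averaged ("positive" = case).  The per-subject
mean predicted label is the fraction of repetitions in which the
subject was predicted "case" while held out.  Significance: labels are
shuffled (default 5000 times) and the mean CV accuracy recomputed with
10 repetitions per shuffle — the permutation distribution of a mean
accuracy is insensitive to the repetition count at this scale — giving
the one-tailed p = (1 + #{perm ≥ observed})/(n_perm + 1).  Contrasts:
case vs control, each subgroup vs controls, subgroup vs subgroup; one
report per (feature set × contrast) with the six single-metric sets
plus the pooled 6·n vector.

A nodal-metric caveat quantified during validation: when planted
effects are uniformly spread over edges, edge-level decoding can be
near-perfect while nodal graph metrics remain near chance — each
node's few affected edges barely move its summary statistics.  Nodal
features become discriminative when dysconnectivity is widespread or
concentrated; the classifier validation cohort therefore reduces 60 of
190 edges by 90%, yielding ~64% pooled accuracy with permutation
p < 0.01 at n = 42 + 42.

## Problem sizes used in validation

The tests and the acceptance script run the full method at reduced,
fixed sizes chosen to keep each check sharp: null calibration on 200
cohorts of 10 nodes / 20 + 20 subjects / 30 s with 1000 permutations;
effect recovery on five cohorts of 20 nodes / 42 + 42 subjects / 150 s
at 120 Hz with 2000 resampling iterations; graph oracles on 50 random
graphs of ≤ 8 nodes; the end-to-end determinism check on 10 nodes /
8 + 8 subjects / 60 s with two bands.  All randomness descends from
`numpy.random.SeedSequence`, so every run is bit-reproducible from its
seed.

## Known limitations

- The vector-sum combined map is sign-folding (see above); analyses
  that depend on effect direction should use per-band normalized maps.
- The split-half consistency criterion has a ~10% null pass rate by
  construction; it is a replicability filter, not a significance test.
- Welch t-statistics are undefined at edges with zero variance in both
  groups (flagged as NaN, never silently dropped).
- The symmetric orthogonalization requires more time samples than
  nodes and full column rank; heavily mixed sources (leakage variance
  comparable to signal variance) cannot be unmixed by any zero-lag
  correction, only decorrelated.
- Classifier defaults (C = 1, z-scoring, 10 permutation repetitions)
  are deliberate fixed choices, not tuned values; no hyperparameter
  search is performed anywhere.
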