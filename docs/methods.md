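# Methods

## Scope and pipeline

`statenet` reimplements, as a tested library, the analysis chain of a
multi-condition source-space MEG study: per-trial directed connectivity by
phase transfer entropy (PTE), condition-level network contrasts by
permutation testing with FDR control, and a multilayer graph whose
off-diagonal blocks record, per subject, which edges co-fluctuate across
task conditions ("multilinks"). The artifact starts at source-space
epochs (trials × nodes × samples with a sampling rate and condition
labels); forward/inverse modelling, artifact correction and atlas
reduction are upstream of it and out of scope. A synthetic-data module
replaces the original recordings so that every stage has a recoverable
planted target.

## Phase transfer entropy

For phases φ_x, φ_y of two signals, the estimator is the plug-in transfer
entropy between binned phases,

    PTE(x→y) = H(y_{t+δ}, y_t) − H(y_t) − H(y_{t+δ}, y_t, x_t) + H(y_t, x_t),

with prediction delay δ (default 10 samples), target history length k = 1,
natural logarithms (nats; downstream use is purely comparative), and joint
histograms over t = 1 … T−δ.

*Phases.* Band restriction and the Hilbert transform are fused into one
frequency-domain step: Fourier coefficients outside the analysis band
(default 2–60 Hz) and at non-positive frequencies are zeroed, retained
positive coefficients are doubled, and the phase is the argument of the
inverse transform. No time-domain filter is applied, so there is no extra
temporal smearing beyond the band restriction itself. One source document
of the upstream preprocessing quotes 2–40 Hz where the connectivity
description says 2–60 Hz; the default here is 2–60 Hz and the band is a
configuration field.

*Bins.* The number of histogram bins partitioning [−π, π] follows the
normal-reference rule recommended for small samples: width
h = 3.49·σ̂·m^(−1/3), bins = ⌈2π/h⌉ (minimum 2), with σ̂ the sample SD of
the trial's pooled phases and m = T−δ the observations per histogram. All
histogram axes of a trial share the bin count. A fixed `bins_override`
exists for reproducibility studies. Note one consequence: because the bin
count grows like T^(1/3), the plug-in bias of PTE under independence does
*not* vanish as epochs lengthen; at a fixed bin count it decays like 1/T
(the property suite checks this at 6 bins). All inference downstream is
comparative (contrasts, correlations), so the shared bias cancels where it
matters.

*Matrices.* Entry (i, j) of a trial's adjacency matrix is PTE(i→j);
phases are computed once per node and reused for all ordered pairs; the
diagonal is zero. Per subject and condition, trial matrices are averaged
and then z-scored over the off-diagonal entries of the averaged matrix
(sample SD). Whether the original analysis z-scored within matrix or
across subjects is not documented; within-matrix is used and recorded in
output metadata.

## Network contrasts

Contrasts are mass-univariate on edges, NBS-style: a paired t across
subjects on (deviant − standard) for within-group condition effects, and
a pooled-variance two-sample t on per-subject difference matrices for the
group × condition interaction (algebraically the 2×2 mixed-model
interaction). Zero-variance edges receive statistic 0 with a warning
rather than ±∞.

Permutation p-values are two-sided with the +1 correction,
p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + P), so p is never zero and the
smallest attainable p is 1/(P+1) — which is why analyses that must clear
a Benjamini–Hochberg threshold of order q/m need P ≫ m/q permutations
(the study's own choice of 10,000 permutations satisfies this for its
designs). The null is generated from sign flips of **mean-centered**
values (one-sample/paired) or label reshuffles of **group-mean-centered**
residuals (two-sample), Freedman–Lane style. Centering matters: flipping
raw values lets a true effect contaminate its own null — measured recall
of planted 1.5 SD edges collapsed from ~0.7 to ~0.2 without it — while
under the null the centering is immaterial (measured false-edge
proportion 4·10⁻⁴ at q = 0.05). Subject rows are canonicalised (sorted)
before the null is drawn, so p-values are invariant to input ordering;
seeded runs are bit-identical.

Edge-level FDR control is Benjamini–Hochberg step-up at level q
(default q = 0.001, the stricter of the two levels the source analyses
report; the multilayer stage uses q = 0.05). Cluster-extent statistics
are deliberately not implemented. Retained edges form a results object
carrying node strength (Σ|statistic| over incident significant edges),
node degree (incident count, in + out) and density (|edges| / N(N−1)).

## Multilayer multilink graphs

For each subject and each ordered pair of conditions A, B, every directed
edge's PTE value per trial in A is Pearson-correlated with the same
edge's values in B. Trials are paired by chronological index after
truncation to the common count — the original pairing convention is
undocumented; a seeded random pairing is available for sensitivity
analysis and the convention is written into output metadata. Each edge's
r is tested two-sided via t = r√((n−2)/(1−r²)); entries failing α
(default 0.05, uncorrected, configurable) are set to zero; positive and
negative correlations are both retained, and raw r (not Fisher-z) is
stored.

The K z-scored condition networks form the diagonal blocks and the
K(K−1)/2 multilink matrices the off-diagonal blocks of a (K·N)×(K·N)
matrix per subject; block (b, a) equals block (a, b) because the edge-wise
correlation is a single number per directed edge. Group inference is a
one-sample t against zero (sign-flip permutations) or a between-group
two-sample t (label permutations), both followed by BH-FDR; the
between-group result is split by sign into the two one-sided contrasts.
Descriptors: per-region multilink degree within a block, connected
components of a thresholded block (each component is one multilink
system), and the intersection of several blocks' masks ("common links").
Reported multilink counts can mean matrix entries or connected
components; both are exposed.

## Synthetic data generator

The generator emulates the *structure the analysis assumes*, not the
biophysics of MEG: the source documents give no generative model for the
recordings, so a delayed-coupling Kuramoto-type phase oscillator network
was chosen because the analysis is phase-mediated and directed. Phases
evolve by an Euler step

    θ_i[t+1] = θ_i[t] + 2π f_i/fs + (1/fs) Σ_j κ_ij^(trial) sin(θ_j[t−d] − θ_i[t]) + ξ,

with transmission delay d = 10 samples (matching the analysis delay),
natural frequencies f_i uniform in 8–12 Hz (inside the analysis band),
process noise ξ ~ N(0, 0.4²) per sample, and observations
x_i = sin θ_i + N(0, 0.05²). Per-trial strengths are
κ^(trial) = κ̄(1 + γu) with u standard normal, γ = 2 by default; for a
multilink edge the draw u of trial k is shared between the two conditions
of its pair (the same chronological-pairing convention the analysis
uses), and independent everywhere else. Mean strengths κ̄ are uniform in
80–120 rad/s; deviant conditions add a configurable `effect` to their
edges.

Three generator design choices deserve explanation, because they were
driven by an estimator property discovered during development. The
histogram-PTE plug-in bias of an edge (x→y) depends on the phase
statistics of the *target* y; when y's locking state swings from trial to
trial, that bias swings too, for **every** source x — so shared trial
modulation leaks into all edges pointing at a multilink target.
Therefore: (i) multilink edges are placed on nodes disjoint from all
other coupling edges (no competing inputs, no cascade paths), (ii) the
process noise default is high enough that the marginal phase distribution
stays near-uniform across locking states (damping the bias modulation
below the per-subject significance threshold; at σ = 0.05 the leak
produced spurious correlations of |r| ≈ 0.45), and (iii) multilink edges
receive the top of the strength range so their direct signal dominates
estimation noise at the epoch lengths the test suite uses. With these
choices the planted co-modulation is recoverable and the false-positive
rate of the surrounding entries matches the nominal α.

What the generator does **not** emulate: volume conduction and source
leakage, 1/f background spectra, evoked transients, amplitude dynamics,
inter-subject anatomical variability. Passing tests therefore demonstrate
the *estimators and inference chain* behave correctly on data satisfying
their assumptions — not that real MEG satisfies those assumptions.

The behavioral generator draws binomial 2AFC counts per subject ×
modality from specified true accuracies (strictly inside (0, 1)), 12
trials per modality by default.

## Behavioral analysis

2AFC proportions are logit-transformed; the chance level 0.5 maps to
exactly 0, so chance-level comparisons are one-sample t-tests against
zero (with Cohen's d = t/√n). Proportions of 0 or 1 are handled by a
Laplace-style shrinkage p' = (k + 0.5)/(n + 1), on by default; the raw
mode errors at 0/1. Group comparisons use the equal-variance pooled t
(the reported df = 23 = 12 + 13 − 2 implies pooling, not Welch) and
Hedges' g = d·(1 − 3/(4·df − 1)); recomputing g from the reported group
means and SDs (0.476/0.406, n=13 vs 0.979/0.484, n=12) reproduces the
reported −1.0930405 to seven decimals. The Group × Modality analysis is
a classical split-plot ANOVA with explicit sums of squares
(subjects-within-group and modality × subjects-within-group error
strata), partial η² = SS_effect/(SS_effect + SS_error), and interaction
df = (m−1, (m−1)(N−g)) — (2, 46) at 25 subjects. With unequal group
sizes the cell-frequency-weighted decomposition is used; the oracle tests
run on balanced designs, where all conventions coincide. One published
behavioral table's SD rows are internally inconsistent with its t and d
values (t = d√n holds; mean/SD does not), so those cells are not used as
fixtures.

## Stimulus paradigm

Stimuli are 4-tuples (shape, color, pitch, timbre) indexed 0–10: pitch
and shape are rigidly coupled (the audiovisual stream), and each index
carries a standard timbre and color through seeded bijections. Six
standard triplet patterns start on six distinct indices; each deviant
category copies a standard pattern and replaces, in the third stimulus
only, the violated feature(s) — timbre (auditory), color (visual), or
shape + pitch together (audiovisual-incongruent) — with the value carried
by the first stimulus of a different standard pattern (the distinct first
indices guarantee a donor exists). The published material does not print
the six patterns' symbol assignments; only the transitional-probability
structure matters downstream, so seeded pseudo-random construction under
the stated constraints is used.

Streams have a familiarisation phase (70 standard patterns) and 3 runs of
460 patterns in which the four categories are *exactly* balanced
(115 each) and randomly interleaved — implemented as a seeded permutation
of the balanced multiset, not i.i.d. sampling, so the stated equality is
guaranteed. Timing (400 ms stimuli, 150 ms ISI) is carried as metadata;
no audio or image rendering is performed. The 2AFC test pairs each
deviant pattern (each used twice) with its source standard: 12 pairs per
modality, order counterbalanced 18/18. Stated phase durations in the
source material are not exactly implied by the stated counts and stimulus
timing; durations are metadata only and never asserted.

## Problem sizes and numerical choices

The test and acceptance suites scale the study down to run on one CPU:
direction recovery uses 100 two-node single-trial simulations at the full
epoch geometry (T = 1921, fs = 1200 Hz, κ = 300 rad/s); null calibration
uses 200 replicates of 10-node null studies with the study's group sizes
(13 and 12) and 1000 permutations; multilink recovery uses 20 replicates
of 15-subject two-condition studies (N = 20 nodes, 60 edges, 5 planted
multilinks, 60 trials, 600-sample epochs, 10,000 permutations at
q = 0.05). Tolerances: estimator-vs-oracle agreement 1e-10; ANOVA/effect
size formula oracles 1e-10; z-scored network mean/SD 1e-9.

Degenerate inputs are defined errors, not silent results: constant
signals (no in-band power), zero phase SD, zero-variance edges (statistic
0 with a warning), constant correlation series (entry 0 with a warning),
fewer than 4 paired trials, incomplete ANOVA cells, and accuracies of
exactly 0 or 1 in the behavioral generator.

## Known limitations

- PTE is the plug-in histogram estimator the study used; no bias
  correction, no dPTE normalisation, no frequency-resolved variant, no
  surrogate-based significance at the single-trial level.
- The adaptive bin rule ties estimator bias to epoch length (see above);
  comparisons across different epoch lengths should fix `bins_override`.
- The oscillator generator is a stand-in, not a claim about cortical
  dynamics; effect sizes recovered from it do not translate to real data.
- With unequal group sizes the split-plot ANOVA uses weighted sums of
  squares; software using Type III conventions may differ in the group
  main effect (never in the balanced-design oracle cases, nor in the df).
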