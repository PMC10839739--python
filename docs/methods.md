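# Methods

This note documents the models, estimators and numerical choices behind
`mdfcn`, what the synthetic cohorts do and do not emulate, and the known
limitations a user should weigh before interpreting results.

## Connectivity estimation

**Band splitting.** Zero-phase band splitting uses a cascade of Butterworth
high-pass (lower edge) and low-pass (upper edge) filters applied
forward–backward (`sosfiltfilt`), so the magnitude response is squared and
phase distortion is zero. The default order is 8 per filter: with the
squared response, a 4th-order cascade loses ~23% of a mid-band tone's power
in an octave-wide band such as θ (4–8 Hz), whereas order 8 keeps the loss
below 5% while attenuating a 6 Hz tone in the β stop-band by more than
60 dB. Signals shorter than the filter's padding requirement are rejected.

**dwPLI.** The debiased weighted phase lag index is computed per 2 s
window from the imaginary parts of the Hann-tapered cross-spectrum at the
DFT bins inside the band (inclusive edges; a band containing fewer than two
bins is an error). The debiased estimator needs replicated observations and
the in-band bins are the only replicates available inside one window; this
choice preserves the per-window temporal resolution of the tensor. Two
consequences matter downstream:

* *Clipping floor.* The debiased estimator is symmetric around 0 under
  independence, and clipping negatives to 0 (required for the non-negative
  factorizations) leaves a positive floor `E[max(0, D)]` of roughly 0.2 for
  the ~9–19 in-band bins of the 2 s window. The floor is a constant offset
  shared by every connection and window; the factorization stages must
  (and do) spend components on it.
* *Chance level.* Statements like "dwPLI tends to 0 for independent
  signals" hold for the estimator evaluated on observations *pooled across
  windows* (the per-window clipped values have the positive floor above and
  their mean does not vanish with more windows). Tests of chance level use
  the pooled form.

Degenerate windows (all-zero imaginary parts, e.g. exactly zero lag) are
stored as 0 by default (`degenerate="zero"`), keeping tensors dense; the
scalar estimator can return NaN instead when asked.

**Geometry.** Pairs are ordered canonically as the row-major upper triangle
(0-based, i < j) in every module. For the reference geometry — 58 parcels,
3 min at 100 Hz, 2 s windows at 50% overlap, 525 masked pairs — the group
tensor is 1128 × 179 N × 5.

## Order selection

Both factorization stages pick their model order with the entropy-based
effective rank `round(exp(H))`, `H = −Σ pₖ ln pₖ`, `pₖ = σₖ/Σσ` over the
positive singular values (of the band slice for NMF; of the
connection-mode unfolding for the CPD), floored at 1 and capped by
configuration (defaults: 40 for NMF, 20 for the CPD, the latter matching
the exhaustive-search cap). Two properties of this selector should be
understood:

* It counts *spectral diversity*, not signal rank: for a planted low-rank
  matrix it returns the true rank only when the singular values are
  comparable (balanced constructions); a random non-negative low-rank
  matrix has a dominant first singular value and yields a smaller number.
* On noise-dominated data it scales with matrix size (measured ~900 of
  1128 uncapped on a realistic simulated group slice), so in practice the
  configured cap acts as the effective order. The caps are therefore real
  modelling parameters: they should be set commensurate with the number of
  connections (a few percent of it mirrors the compression ratio of
  published cohort-scale analyses).

## Factorizations

**NMF.** Hierarchical alternating least squares with exact block updates
(objective non-increasing per sweep), NNDSVDa initialization for the first
restart and seeded random restarts otherwise (default 5 restarts, tol 1e−6
on the relative Frobenius improvement, max 500 sweeps). The latent tensor
stores the reconstruction `W·H` per band.

**Non-negative CPD.** Alternating least squares over the three modes with
HALS inner column updates, SVD-magnitude initialization for restart 0,
seeded random restarts otherwise (default 5 restarts, tol 1e−7, max 1000
sweeps). Columns of the connection and band factors are normalized to unit
sum with the scale absorbed into the temporal factor, which leaves the
reconstruction unchanged. Components whose factors collapse to zero are
dropped with a warning and R reduced. CPD identifiability is up to
permutation and scale; recovery tests match columns by greedy maximum
cosine similarity. Block averaging divides the temporal factor into the
per-subject window blocks and takes means, turning components into
connection × subject × band descriptions.

## Selection and statistics

Standardization removes each subject's median connectivity and divides by
the raw median absolute deviation (no 1.4826 consistency factor — the
convention is literal MAD = 1). Partial Spearman correlation rank-transforms
all three variables (average ranks on ties) and applies the one-covariate
partial Pearson formula on the ranks, with two-sided p-values from the t
approximation with n − 3 degrees of freedom. BH adjustment is delegated to
statsmodels; the family is all reliable connections within one
(band, score, direction) analysis. The fitness is the geometric mean of
density, mean |ρ| over significant connections, and the mean per-connection
OLS R² against the score. Ties in the exhaustive subset search resolve to
the smaller subset, then lexicographically. Subjects missing the requested
score or the age covariate are dropped from selection only; tensors retain
everyone.

The permutation null shuffles the subject columns of the connectivity
matrix jointly — preserving the inter-connection dependence — and
recomputes the full correlation + FDR pipeline per permutation (default
10,000). Note that BH rejections under the null are positively dependent
(the step-up threshold adapts to the smallest p-values), so null densities
cluster: a binomial model with the estimated per-connection rate matches
the probability of *any* rejection well but underestimates the probability
of two or more.

## Synthetic cohorts

The generator synthesizes band-limited signals directly (white noise
filtered into each band and normalized), because the pipeline consumes
band-split parcel signals; no electrode-level or head-model simulation is
attempted. Three ingredients:

* **Score-linked coupling.** Each planted edge adds a shared band-limited
  component to one parcel and a Hilbert-phase-shifted copy (constant lag)
  to the other, scaled by `coupling_gain` times a per-subject strength.
  Strengths are a fixed uniform grid (default 0.2–1.0) assigned through a
  Gaussian copula whose Pearson parameter `2 sin(π ρ/6)` makes the
  expected Spearman correlation with the emitted score equal `score_link`.
  A constant non-zero lag yields a same-sign imaginary cross-spectrum, the
  dwPLI → 1 regime.
* **Idiosyncratic background coupling.** Every subject also receives weak
  phase coupling on a random quarter of the parcel pairs (amplitudes
  uniform up to half the noise SD, random lags), independent of the score.
  This emulates the intersubject variability that dominates real cohorts;
  without it, the score-linked coupling is the only subject-level variance
  in the tensor, every factor loading aligns with it, and the null model
  is unrealistically easy.
* **Covariate.** Conceptional ages are uniform in 40–44 weeks and
  independent of the score, so the covariate is non-confounding unless the
  user links it.

Not emulated: EEG artifacts, sleep-state dynamics, electrode-level mixing
and head-model leakage, spatial structure in the fidelity mask (rejections
are uniform). Passing tests on these cohorts therefore demonstrate the
pipeline's behaviour under controlled coupling and heterogeneity, not
robustness to real-world recording confounds.

## Edge-level specificity (known limitation)

The pipeline reliably *recalls* planted score-linked connections (pooled
recall above 0.8 in the end-to-end recovery test), but its edge-level
*precision* is intrinsically limited, and the corresponding acceptance
test is intentionally left failing rather than weakened. The mechanism,
reproducible even with a noise-free planted tensor fed straight to the
CPD and selection stages:

* a reconstruction from a subset of components lies in an R-dimensional
  subject-loading space with essentially no per-connection residual noise;
* Spearman correlation is scale-free, so *any* non-zero leak of a null
  connection's loading onto a score-correlated component produces
  |ρ| ≈ |corr(loading, score)| regardless of the leak's magnitude;
* such leaks are unavoidable: the clipped-dwPLI floor is a flat background
  shared by all connections, and the non-negative factorization of
  "background + score-modulated increment" is non-unique (any non-negative
  basis of their span fits equally well), so null connections always carry
  some mass on the score-linked component.

Roughly half the null connections end up significant in the positive
direction and half in the negative. This behaviour is consistent with the
dense networks (densities up to ~60%) that cohort-scale applications of
this family of methods report: the method identifies dense score-linked
network constellations at the group level; individual edges inside them
should not be read as specific discoveries. The permutation-based density
null and the 2.5% density floor guard against analyses where *nothing* is
linked to the score, but the floor does not control the multiplicity of
the exhaustive subset search — under pure-noise scores a spurious
supra-floor density still appears in a minority of runs (rate depending on
cohort size and component count).

## Multiplex measures

With layer degrees `k_i^α`, overlapping degree `o_i = Σ_α k_i^α`
(normalized by `M(N−1)`), participation
`P_i = M/(M−1) · (1 − Σ_α (k_i^α/o_i)²)` (0 for isolated nodes), pairwise
multiplexity = fraction of nodes active in both layers, Hamming distance =
edge symmetric difference over the number of reliable pairs, total overlap
ratio = fraction of union edges present in ≥ 2 layers, and edge
intersection index = |∩ layers| / |∪ layers|. Empty layers and empty
unions return 0 so group averaging stays defined. An edge-overlap variant
of pairwise multiplexity is intentionally not the default; node activity
is the implemented convention.

## Problem sizes used in the test suite

All tests run on synthetic data generated at call time. The heavier checks
use: CPD recovery at the cohort-like aspect ratio 1128 × 1790 × 5 with
R = 5 and 5% noise (5 seeds, single restart, ≤ 100 sweeps); end-to-end
recovery on 16-parcel / 2-band / 60 s cohorts of 40 subjects (10 seeds,
rank caps 40/12 scaled to the 120-connection geometry, coupling amplitude
three times the background SD); FDR calibration on 200 replicates of 200
independent null connections at N = 40. These sizes are the package's
validation conditions; conclusions at other scales follow from the theory
above, not from the tests.
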