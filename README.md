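# mdfcn — multiplex dynamic functional connectivity networks

`mdfcn` implements a group-level analysis pipeline for linking the rapidly
fluctuating, frequency-specific functional connectivity of the newborn brain
to neurobehavioral phenotype scores. It is written for researchers working
with source-reconstructed EEG (or MEG) parcel time series who want to go
from band-filtered signals to phenotype-correlated multiplex networks with
every intermediate stage inspectable and testable.

## The method

Starting from per-subject parcel signals split into five frequency bands
(low-δ 0.4–1.5, high-δ 1.5–4, θ 4–8, α 8–13, β 13–22 Hz, sampled at
100 Hz), the pipeline proceeds in six stages:

1. **Dynamic connectivity.** Signals are segmented by a 2 s sliding window
   with 50% overlap (179 windows for a 3 min recording). For every parcel
   pair and window, phase synchronization is estimated by the debiased
   weighted phase lag index over the in-band DFT bins of the Hann-tapered
   cross-spectrum:

   `dwPLI = ((Σᵢ Iᵢ)² − Σᵢ Iᵢ²) / ((Σᵢ |Iᵢ|)² − Σᵢ Iᵢ²)`

   where `Iᵢ` are the imaginary cross-spectral parts. The estimator is 1
   exactly when all observations share one sign (constant non-zero phase
   lag) and is blind to zero-lag (volume-conduction) coupling. Negative
   debiased values are clipped to 0. Per subject this yields a
   1653 × 179 × 5 tensor (58 parcels); a fidelity mask removes unreliable
   pairs (525 in the reference geometry, leaving 1128) and subjects are
   concatenated along the window mode into a group tensor of size
   1128 × 179 N × 5.

2. **Latent extraction.** Each band slice is approximated by non-negative
   matrix factorization (HALS, NNDSVDa initialization, best of restarts)
   at a rank chosen by the entropy-based effective rank
   `round(exp(−Σ pₖ ln pₖ))`, `pₖ = σₖ/Σσ`, of the slice's singular
   values. The reconstruction `W·H` — not the factors — is the latent
   tensor; it suppresses window- and subject-level noise.

3. **Tensor decomposition.** The latent tensor is decomposed by
   non-negative canonical polyadic decomposition (ALS with HALS inner
   updates) into R rank-1 components `aᵣ ∘ bᵣ ∘ cᵣ` (connection ×
   time/subject × band factors), R again chosen by the entropy criterion.
   Temporal factors are block-averaged within each subject's window block,
   giving one loading per subject.

4. **Component selection.** For every non-empty component subset, a
   connection × subject network is reconstructed per band, standardized
   per subject (median removed, raw MAD set to 1), and each connection is
   correlated with the phenotype score by partial Spearman correlation
   controlling for conceptional age, with Benjamini–Hochberg FDR at 5%.
   The subset maximizing the geometric-mean fitness
   `F = (density · mean|ρ| · mean R²)^{1/3}` is kept, separately for
   positively and negatively correlated networks; densities below 2.5%
   are discarded as empty.

5. **Calibration.** A permutation null (default 10,000 subject
   permutations) yields the distribution of network densities expected by
   chance; group score differences use the two-tailed Wilcoxon rank-sum
   test.

6. **Multiplex cartography.** Significant connections per band form the
   layers of a binary multiplex graph over the parcels, summarized by the
   normalized overlapping degree, multiplex participation coefficient,
   pairwise multiplexity, Hamming distance, total overlap ratio and edge
   intersection index.

A synthetic-cohort simulator (`mdfcn.cohortsim`) generates band-limited
parcel signals with planted, score-linked phase coupling plus
subject-idiosyncratic background coupling, so every stage can be validated
against known ground truth.

## Worked example

```python
import numpy as np
from mdfcn import (SyntheticConfig, BandScheme, generate_cohort,
                   generate_fidelity_mask, subject_tensor, build_group_tensor,
                   extract_latent, subject_cpd, select_components)

scheme = BandScheme((("theta", 4.0, 8.0), ("alpha", 8.0, 13.0)))
cfg = SyntheticConfig(
    n_subjects=20, n_parcels=10, duration_s=60.0, fs=100.0, band_scheme=scheme,
    planted_edges=[(0, 1, 0, np.pi/2), (2, 3, 0, np.pi/2), (4, 5, 0, np.pi/2)],
    coupling_gain=3.0, score_link=0.8, seed=42,
)
cohort, phenotypes, truth = generate_cohort(cfg)
mask = generate_fidelity_mask(45, 5, seed=42)
tensors = [subject_tensor(b, cfg.fs, scheme) for b in cohort.subjects.values()]
group = build_group_tensor(tensors, mask, subject_ids=cohort.subject_ids)
latent = extract_latent(group, seed=0, rank_cap=10)
model = subject_cpd(latent, seed=0, order_cap=8)
res = select_components(model, phenotypes, "score", band=0, direction="pos")
```

With this seed the run prints:

```
group tensor: (40, 1180, 2)
NMF ranks per band: [10, 10]
CPD order: 8 (relative fit error 0.374)
selected components: (2, 3, 7)
density 0.550, mean |rho| 0.673, mean R^2 0.522, fitness 0.578
```

Read: 40 reliable connections × (59 windows × 20 subjects) × 2 bands enter
the factorization; the θ-band network reconstructed from components
{2, 3, 7} has 55% of its connections significantly and positively
correlated with the synthetic score (mean partial ρ of 0.67) after age
correction and FDR. Because the coupling was planted only in θ, the α
layer stays empty and the multiplex participation coefficient of the
active nodes is 0 — a maximally frequency-focused network.

The same stages are exposed as a CLI:

```bash
mdfcn simulate --config sim.yaml --out cohort/ --seed 1
mdfcn connectivity --signals cohort/signals.h5 --mask cohort/mask.csv --out group.h5
mdfcn extract --group group.h5 --out latent.h5 --seed 1
mdfcn decompose --latent latent.h5 --out cpd.h5 --seed 1
mdfcn select --model cpd.h5 --phenotypes cohort/phenotypes.csv --score score --out sel/
mdfcn run --config run.yaml          # everything, with a JSON run report
```

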