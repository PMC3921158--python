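# plinet

Phase-lag-index functional connectivity and weighted brain-network
analysis for multichannel resting-state EEG, with a seeded
coupled-oscillator cohort simulator.

`plinet` is aimed at researchers who want to quantify band-specific
synchronization between scalp electrodes in a way that is robust to
volume conduction, and to summarize the resulting connectivity matrices
as weighted graphs. It covers the full chain: band filtering and
epoching, Hilbert phase extraction, PLI/dPLI connectivity, frontal and
posterior cluster summaries, surrogate-normalized clustering coefficient
and path length, small-world index, and two-group statistics. Because
clinical resting-state EEG is rarely shareable, the package also ships a
synthetic-cohort generator with known, band-specific phase-lag coupling,
so every stage of the pipeline can be validated against ground truth.

## The measures

For two channels with instantaneous phases φ₁(t), φ₂(t) (argument of the
Hilbert analytic signal of the band-filtered data), the **phase lag
index** is

    PLI = | ⟨ sign(Δφ(t)) ⟩ₜ |,   Δφ wrapped to (−π, π]

PLI ∈ [0, 1]; it is 0 for no coupling or for coupling at exactly zero
(or π) lag, and 1 for perfect locking at any other lag — instantaneous
(volume-conducted) correlations therefore do not inflate it. The
**directed PLI** is the time-average Heaviside step of Δφ (H(0) = ½):
0.5 means no lead/lag asymmetry, above 0.5 the first channel leads, and
|2·dPLI − 1| = PLI.

Taking electrodes as nodes and PLI values as symmetric edge weights
w_ij, the **weighted clustering coefficient** of node i is

    C_i = Σ_{k≠l} w_ik w_il w_kl / Σ_{k≠l} w_ik w_il   (k, l ≠ i)

and the **weighted path length** between nodes is the Dijkstra shortest
path under the distance transform d_ij = 1/w_ij, both averaged over the
network (C_w, L_w). Raw values depend on overall connectivity level, so
they are normalized by their means over 50 edge-shuffled surrogate
networks (weight multiset preserved): C_w/C_s, L_w/L_s, and the
small-world index S = (C_w/C_s)/(L_w/L_s).

Group contrasts use two-tailed pooled-variance t-tests on
log-transformed measures with partial eta squared (t²/(t²+df)) as the
effect size; an a-priori power analysis inverts the noncentral-t power
curve of the two-sample test.

## Worked example

Simulate one subject from the FXS-like template (elevated
fronto-posterior theta coupling), extract theta-band connectivity, and
normalize the graph metrics:

```python
import numpy as np
from plinet import (BAND_BY_NAME, bandpass, cluster_means,
                    connectivity_matrix, fxs_like_template,
                    generate_recording, global_mean_pli,
                    instantaneous_phase, make_epochs, normalize_metrics,
                    WeightedGraph)

tpl = fxs_like_template()
rec = generate_recording(tpl.base_config, tpl.couplings, seed=7)

theta = BAND_BY_NAME["theta"]
epochs = make_epochs(bandpass(rec, theta))          # 6 epochs x 4096 samples
phases = [instantaneous_phase(e, epochs.channels) for e in epochs.epochs]
mat = connectivity_matrix(phases, "pli", theta)     # 26 x 26, epoch-averaged

cc = cluster_means(mat)
print(f"global theta PLI     : {global_mean_pli(mat):.3f}")
print(f"fronto-posterior     : {cc.long_range:.3f}")

rng = np.random.default_rng(1)
metrics = [normalize_metrics(WeightedGraph(connectivity_matrix(p).values,
                                           mat.channels), 50, rng)
           for p in phases]
print(f"normalized Lw        : {np.mean([m.path_length_norm for m in metrics]):.3f}")
```

Output:

```
global theta PLI     : 0.147
fronto-posterior     : 0.239
normalized Lw        : 1.064
```

The long-range (frontal x posterior electrode pairs) theta PLI sits well
above the 26-channel global mean because six fronto-posterior pairs
carry explicit phase-lag coupling in this template, and the normalized
path length exceeds 1 because those few strong edges make the weight
distribution heterogeneous relative to its edge-shuffled surrogates.

The same analysis runs end to end from the command line:

```bash
plinet simulate --seed 1 --out cohort/         # ASCII epochs + manifest
plinet run --config pipeline.yaml --out results/
```

producing per-subject-per-band measures (`subject_measures.tsv`) and a
group-statistics table (`group_stats.tsv`).

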