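# Methods

This note documents the models, numerical choices and limitations behind
`plinet`, in the order the pipeline applies them.

## Signal model of the synthetic cohorts

Each simulated channel is a sum of six narrow-band oscillators (one per
analysis band) plus a 1/f background:

    x_c(t) = Σ_b a_b · cos(φ_{b,c}(t)) + η · n_c(t)

The phase of band b on channel c evolves as a detuned random walk,

    φ_{b,c}[n+1] = φ_{b,c}[n] + 2π f_{b,c} / f_s + σ_b ε[n],  ε ~ N(0, 1)

with the channel's natural frequency f_{b,c} drawn uniformly from
`freq ± freq_spread` once per recording. Two mechanisms decorrelate
uncoupled channels: the detuning sweeps their phase difference through
2π, and the diffusion term (σ_b, rad/√sample) broadens the line. Both
are needed: detuning alone leaves occasional near-degenerate pairs
phase-locked for a whole epoch, diffusion alone decorrelates too slowly
inside a narrow band. Defaults scale with the band's width (e.g. theta
σ = 0.10, spread 1.2 Hz; beta σ = 0.22, spread 4 Hz), mirroring the
broader spectral peaks of faster rhythms. The background is spectrally
shaped white noise with power ∝ 1/f, normalized to unit variance and
scaled by `noise_amplitude` (default 0.1, small relative to the
unit-amplitude band components so that analytic test cases stay crisp).

A fundamental constraint worth stating: the PLI estimated from T seconds
of a process with effective bandwidth B has a positive sampling bias of
roughly √(2/(π·B·T)) even for truly independent signals. At one
4096-sample epoch (8.192 s at 500 Hz) this floor is ≈ 0.13 in the 4 Hz
wide theta band and ≈ 0.07 in the 17 Hz wide beta band — the same order
as the background PLI levels seen in real resting-state EEG. Tests that
assert near-zero PLI for uncoupled channels therefore run in the beta
band, where the time-bandwidth product makes the bound attainable; in
narrow bands the uncoupled level is reproducibly ≈ 0.10–0.15 and group
contrasts ride on top of it.

### Coupling

A `CouplingSpec` pins the follower channel's band phasor partway onto
the leader's phase minus a lag:

    φ_f := angle((1 − s)·e^{iφ_f,free} + s·e^{i(φ_l − lag)})

Strength s = 1 with zero diffusion produces a constant lag (downstream
PLI exactly 1), s = 0 leaves the phases independent, and the realized
PLI is monotone in s (checked over {0, .25, .5, .75, 1} averaged across
seeds). The default lag is π/4 — far from both 0 and π, where the PLI
is blind. Couplings are applied in list order, so chained specs see the
already-pinned phases of earlier ones.

### Group templates

Templates are parameterized by direction, not magnitude, because no
quantitative effect sizes exist to calibrate against. The FXS-like
template couples six fronto-posterior channel pairs in theta at strength
0.75 and thirteen whole-head disjoint pairs in upper alpha and beta at
0.30; the control-like template uses 0.35 / 0.65 / 0.60 respectively.
These choices produce the qualitative contrast of interest — higher
long-range theta connectivity, lower diffuse upper-alpha/beta
connectivity, and a longer normalized theta path length in the FXS-like
group (the concentrated strong theta edges make the weight distribution
heterogeneous; edge-shuffled surrogates redistribute them into
shortcuts, so L_w/L_s rises above the more homogeneous control value).

Zero-lag mixing (volume conduction) is modelled as an instantaneous
matrix multiply, kept separate from coupling: it raises amplitude
correlation and spectral coherence between channels without creating
nonzero-lag phase structure, which is precisely what the PLI discards.

Per-subject seeds derive from `SeedSequence([master_seed, group_index,
subject_index])`, so cohorts are bit-reproducible and stable under
reordering.

## Preprocessing

Filtering uses a 4th-order Butterworth per pass, applied
forward-backward (`sosfiltfilt`), i.e. zero-phase with doubled effective
order — stable even for the 0.5–4 Hz band at 500 Hz. The order of
operations is filter-the-continuous-recording → cut epochs → Hilbert per
epoch. Epochs are contiguous, non-overlapping, and taken from the start
of the recording; the default geometry is six epochs of 4096 samples.
Instantaneous phase is the angle of the analytic signal, wrapped to
(−π, π]; an all-zero channel raises, since its phase is undefined.
Hilbert edge effects contaminate a few samples per epoch edge; tests
that fit phase slopes exclude the outer 5% of each epoch, while PLI
itself uses all samples (the contamination is negligible at 4096
samples against the tolerances used).

## Connectivity

PLI uses sign(0) = 0 and dPLI uses H(0) = ½, which keeps the identity
|2·dPLI − 1| = PLI exact on degenerate zero-lag samples. Internally the
wrap of the phase difference is folded into the sign function
(piecewise, no modulo pass) — algebraically identical, and it keeps the
26×26×4096 pairwise tensor cheap. The sign convention is
Δφ = φ_first − φ_second, so dPLI > 0.5 means the first channel leads.
Subject matrices are entrywise means of per-epoch matrices. dPLI is
computed and reported but never fed to the graph metrics, which are
defined on the symmetric PLI weights.

Cluster summaries pool a 7-electrode frontal set (Fp1, Fp2, F7, F3, Fz,
F4, F8) and a 6-electrode posterior set (P3, Pz, P4, O1, Oz, O2): 21
within-frontal, 15 within-posterior and 42 cross pairs. The default
montage retains its asymmetric FC6-without-FC5 layout verbatim;
both montage and clusters are overridable in the pipeline config.

## Graph metrics and normalization

Clustering follows the symmetric-weight triple-sum form (isolated nodes
get 0); the vectorized implementation reduces to diag(W³) over
(row-sum² − row-sum-of-squares) and is verified against a naive
triple loop to 1e−12. Path length uses Dijkstra
(`scipy.sparse.csgraph`) on distances 1/w, averaged arithmetically over
ordered node pairs excluding i→i; a zero weight means the edge is
absent, and an unreachable pair raises an explicit error naming the
nodes rather than being assigned a silent large value (full PLI matrices
have no exact zeros in practice, but the simulator can produce them).

Surrogates permute the upper-triangle weights uniformly and mirror them,
preserving the weight multiset exactly; 50 surrogates by default. A
disconnected surrogate is discarded, logged, and redrawn. On a
triangle-free sparse graph the surrogate clustering can average zero, in
which case the normalized clustering is reported as NaN rather than an
arbitrary number. For graphs with i.i.d. weights, shuffling reproduces
the generative law and all three normalized quantities calibrate to
1 ± 0.05 (checked over 20 graphs of 26 nodes). The surrogate RNG stream
is separate from the simulation stream, so connectivity results are
unchanged by normalization settings. Small-worldness is reported as the
raw index S = (C_w/C_s)/(L_w/L_s) without a hard classification label;
the conventional reading is S > 1 together with C_w/C_s > 1.

Graph metrics are computed per epoch, normalized, then averaged over
epochs (default); a config switch (`graph_level: subject_mean`) computes
them once on the epoch-averaged matrix instead, for sensitivity
analysis.

## Statistics

Group comparisons are two-tailed pooled-variance (Student) t-tests on
natural-log-transformed measures — the pooled form is what a df of
n₁+n₂−2 implies, and the log base is immaterial to t. No
multiple-testing correction is applied; the run manifest records the
number of tests performed. Partial eta squared is t²/(t²+df). The
power analysis computes two-sample two-sided power under the noncentral
t distribution with noncentrality d·√(n/2) and df = 2n−2, and searches
the smallest integer n per group reaching the target (d = 0.8, α = .05,
power = .80 → n = 26); it agrees with statsmodels' continuous solver
after ceiling. The default group-stats table covers five measures per
band — global PLI, long-range cluster PLI, normalized clustering,
normalized path length, and S — chosen as the headline quantities of
the analysis; the short-range cluster measures remain in the
per-subject table and can be added via `stat_measures`.

## Problem sizes used in the test suite

The replicate-based checks use sizes chosen to keep the full suite
fast while preserving the cohort geometry: direction-of-effect recovery
runs 20 replicate cohorts of 8 FXS-like vs 12 control-like subjects
(6 epochs × 4096 samples each), computing theta long-range PLI and
per-epoch theta graph metrics with 50 surrogates, plus upper-alpha and
beta global PLI — the three bands the directional claims concern.
Type-I calibration runs 500 null-cohort replicates on a reduced
4-channel, single-band, one-epoch configuration, which preserves the
statistical pathway (simulate → PLI → log → pooled t) at a fraction of
the cost.

## What the simulator does and does not emulate

It emulates: band-limited oscillatory channels with realistic spectral
peaks, controllable pairwise phase-lag coupling per band, zero-lag
linear mixing, 1/f background, and two-group cohort structure. It does
not emulate: biophysical neural-mass dynamics, realistic head-model
lead fields, artifacts (blinks, muscle), non-stationarity across the
recording, or laterality structure. Passing tests therefore demonstrate
that the analysis chain recovers known phase-lag structure and its group
contrasts under idealized conditions — not that it would detect the
same contrasts at real-data signal-to-noise ratios, where artifact
rejection and reference choices add variance the simulator does not
model.

## Known limitations

- The PLI sampling floor (above) means absolute PLI levels in narrow
  bands are biased upward at the default epoch length; comparisons
  between groups analysed identically are unaffected.
- The ASCII reader expects one epoch per file with samples as rows; the
  EDF writer is a minimal 16-bit encoder (integer sampling rates, whole
  seconds) intended for round-tripping synthetic cohorts, not as a
  general-purpose exporter.
- `log_transform` rejects non-positive values by design; a measure that
  is exactly zero (possible for degenerate PLI summaries) must be
  handled upstream before group statistics.
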