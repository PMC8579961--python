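# Methods notes

This note records how each stage is computed, which conventions were chosen
where several are in circulation, and what the synthetic generator does and
does not emulate.

## Spectral estimation and connectivity

Epochs are taken as given (cleaned, artifact-free); the package performs no
ICA, re-referencing or notch filtering. Each epoch is Hann-tapered
(periodic window) and Fourier-transformed; a band collapses the per-epoch
cross-spectral density over its FFT bins **before** the epoch-wise
estimator runs (`band_collapse="bins_then_epochs"`). The alternative —
estimator per bin, averaged afterwards — is available as
`"epochs_per_bin"`; the two agree exactly for single-bin bands and differ
slightly otherwise because the estimators are nonlinear.

Band membership is half-open, `f_lo <= f < f_hi`. Adjacent bands (delta
1–4 Hz, theta 4–7 Hz, …) would otherwise share their boundary bin, and a
genuine theta effect would then leak a group difference into the delta
family. At the default 4-s epochs the bin spacing is 0.25 Hz.

WPLI is `|Σ a_t| / Σ |a_t|` with `a_t` the per-epoch imaginary
cross-spectrum; DWPLI is the cross-epoch pairwise-product estimator
`((Σ a)² − Σ a²) / ((Σ|a|)² − Σ a²)`, the debiased estimator of squared
WPLI. It needs at least two epochs, can be negative, and is never clipped:
under independence it is zero-mean, so clipping would bias group averages
upward. Pairs with no imaginary cross-spectral energy (zero denominator)
are set to 0 — no detectable lagged coupling — and counted in a log
message. The single-pair null standard deviation at 75 epochs is roughly
0.04, so individual null entries of ±0.1 are unremarkable even though the
mean over pairs sits near 0.

`bandpass_epochs` (4th-order Butterworth, `sosfiltfilt`, per epoch, scipy's
default odd-symmetric padding) is provided for time-domain uses; the
connectivity path band-limits in the frequency domain and does not filter
first.

Regional averaging follows a 10-region scheme (left/right prefrontal,
temporal, parietal, central; medial parietal; occipital) over the 60 scalp
channels of a 64-channel montage; the four non-scalp leads (M1, M2, CB1,
CB2) are dropped by default, and the channel list is configurable.

## Classical graph metrics

The proportional threshold keeps the top `round(p·E)` of the `E = N(N−1)/2`
connections (`p = 0.10` by default; rounding is half-away-from-zero; ties
at the cut break by (i, j) lexicographic order and are logged; negative
weights rank below all positive ones). On 60 nodes this keeps 177 of 1770
edges.

Weight-to-length conversion is `d = 1/W` throughout: strong connections are
short paths. Characteristic path length averages finite shortest lengths
only (disconnected ordered pairs are excluded and counted — disconnection
is routine at a 10% threshold); global efficiency uses `1/∞ = 0` and so
needs no exclusion.

Clustering uses the plain triple-product form
`C_i = Σ W_ik W_il W_kl / Σ W_ik W_il` (sums over `k ≠ i`, `l ≠ i, k`),
which scales linearly in the weights. The cube-root (Onnela) variant is
available via `clustering_variant="onnela"`. Local efficiency uses
`(W_ij W_ih / d_jh(N_i))^(1/3)` over neighbour pairs, with `d_jh(N_i)` the
shortest length within i's neighbourhood, normalised by the *binary*
neighbour count `k_i(k_i − 1)` and a `1/(2N)` prefactor; the binary count
is the standard convention and keeps the quantity scale-linear, whereas a
weighted-degree normaliser would not be.

Surrogate networks reshuffle the upper-triangle weight multiset uniformly
(preserving symmetry, diagonal and the exact multiset); `γ = C/C_random`,
`λ = L/L_random`, `σ = γ/λ` use the means over 50 surrogates by default.
Very sparse thresholded graphs (small N at p = 0.10) can leave surrogates
with no triangles at all, making `C_random = 0`; this raises an explicit
undefined-normalisation error rather than returning infinity — raise the
threshold proportion for small networks.

## Spanning-tree metrics

The tree is the maximum-weight spanning tree of the **full** DWPLI matrix
(not the thresholded graph, which is generally disconnected), built by
Kruskal's algorithm with union-find on descending weights; ties break
lexicographically, negative entries are valid weak candidates, exact zeros
mean "no edge". Tree topology is then unweighted (path lengths in edges).
With `M = N − 1` edges: `K_max = max degree / M`, `Lf = leaves / M`,
`D = diameter / M`, `ECC = mean eccentricity / M`, `BC = max betweenness /
((N−1)(N−2)/2)`, and `Th = Lf / (2·BC)`. ECC is the mean over nodes and BC
the maximum over nodes; these conventions reproduce the magnitude ranges
reported for 60-channel resting EEG trees (Lf ≈ 0.5, D ≈ 0.28, ECC ≈ 0.22,
K_max ≈ 0.11, BC ≈ 0.66, Th ≈ 0.37).

## Group statistics

Mann–Whitney U is two-sided; the exact null distribution is used when the
combined sample is at most 20 without ties, the tie-corrected normal
approximation otherwise. A constant feature returns p = 1 (logged) rather
than failing. FDR correction is Benjamini–Hochberg within one family per
condition × band × feature class (connectivity vs topology), mirroring how
such tables are usually corrected; the family map is configurable. Pre/post
change is `100·(post − pre)/pre` per subject and feature, compared across
groups the same way.

## Classification

Random forest with recursive feature elimination, evaluated by
leave-one-out cross-validation. RFE refits on the training subjects of
every fold — feature selection never sees the held-out subject — and a
fresh seeded forest predicts it; pooled predictions form one confusion
matrix (aMCI is the positive class). Defaults: 200 trees, RFE step 0.2
(fraction of features removed per iteration), 20 selected features;
`n_select="auto"` picks from {5, 10, 20, 40} by out-of-bag score on the
training fold. A step fraction with a fixed target is preferred over
one-at-a-time elimination because LOOCV multiplies every RFE fit by the
number of subjects; with several hundred features the two orderings select
near-identical sets at a small fraction of the cost. Forests are
scale-invariant, so features are not standardised and MMSE enters as a raw
integer.

## Synthetic cohorts

The generator builds signals directly in the frequency domain, per epoch:

* **background**: independent 1/f noise per channel (amplitude
  `∝ f^(−β/2)`, β = 1 by default);
* **coupling**: each coupled pair shares a band-limited random-phase
  source; the second channel receives it rotated by the pair's phase lag.
  The default layout couples 60 random theta pairs (lags around ±π/2, SNR
  near 1) and 40 low-alpha pairs shared identically by both groups;
* **group effect**: patient-group theta coupling amplitudes are multiplied
  by `group_effect = 0.70`, calibrated once against the target of a
  20–23% reduction in group-mean global theta DWPLI under the default
  conditions (60 channels, 75 four-second epochs at 250 Hz) and then
  frozen. Measured response at those conditions: factor 0.55 → ≈40%
  reduction, 0.62 → ≈31%, 0.70 → ≈21%;
* **subject variability**: per-subject, per-pair lognormal amplitude
  jitter (σ = 0.2);
* **volume conduction**: an instantaneous mixing matrix
  `(1−a)·I + a·K` (a = 0.15, K a random nonnegative kernel) applied to all
  channels — it induces strong zero-lag correlations that DWPLI must, and
  does, ignore;
* **MMSE**: integer scores from truncated normals on [0, 30] with group
  parameters 23.86 ± 3.32 (patients) and 27.45 ± 1.72 (controls);
* **conditions**: `post` is an independent realization of the same model;
  condition-specific effects are opt-in via `post_effects`.

Defaults follow the study conditions: 43 patients / 51 controls, 60
channels, 75 epochs. The sampling rate defaults to 250 Hz; estimates
depend on band content, not the rate, and this is asserted in the tests.

What the generator does **not** emulate: neural dynamics (sources are
linear band-limited noise, not oscillators), realistic head-model mixing,
non-stationarity across epochs, artifacts, or any amplitude–phase
relationship between bands. Passing recovery tests therefore show that the
estimator/statistics chain detects the kind of lagged-coupling group
difference it is designed for — not that real aMCI data would behave this
way.

## Problem sizes in tests and reproduction runs

Statistical property tests and the end-to-end recovery checks run on
reduced cohorts chosen to keep the full suite in a few minutes of one CPU:
recovery uses 30+30 subjects, 30 channels, 40 epochs over 20 seeds (the
calibrated reduction is ≈20% there as well); classification uses one 15+15
subject cohort at 60 channels and 40 epochs with 50-tree forests over 10
classifier seeds; surrogate counts drop to 20 where normalised metrics are
incidental. `scripts/acceptance.py` uses the same reduced sizes and
reports the size next to every value.

## Numerical notes

* `(Σa)² − Σa²` in DWPLI loses relative precision when epochs mix
  magnitudes across many orders; errors stay near machine epsilon in
  absolute terms and are irrelevant at estimation noise levels.
* All randomness (surrogates, forests, generator) flows from explicit
  seeds; identical config + seed gives byte-identical CSV outputs.
* MST and threshold tie-breaks are deterministic (lexicographic), so equal
  weights cannot reorder results between runs.

## Limitations

* Sensor-space analysis only; no source reconstruction, leadfield modeling
  or leakage correction beyond DWPLI's own zero-lag immunity.
* The clustering coefficient's triple-product form and the local-efficiency
  prefactor follow one published convention; values are not numerically
  comparable to toolboxes using the Onnela form (the config flag exists for
  that comparison).
* Confidence intervals for group means are not computed; the comparison
  surface is rank-based.
* The classifier grid is deliberately small; this is a reference
  implementation of the RFE + LOOCV protocol, not a tuned clinical model.
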