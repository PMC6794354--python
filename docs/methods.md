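# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `ecnet`, in the order the pipeline applies them.

## Montage

The analysis montage has 29 channels in eleven regions (PFC: Fp1/Fp2,
mPFC: Fpz, VLPFC: F7/F8, DLPFC: F3/F4, FC: FC5/FC1/FC2/FC6, mFC: Fz/Cz,
TC: T7/T8/P7/P8, PC: C3/C4/CP5/CP1/CP2/CP6/P3/P4, mPC: Pz, OC: O1/O2,
mOC: POz), hemisphere assignment by the 10-20 naming rule (odd = left,
even = right, z = midline). Reference (CPz) and ground (AFz) are not
analysis channels.

Electrode coordinates are **idealized**, not measured: the 10-20 outer
ring sits on the equator of a unit sphere, midline/central rows at 45°
from the vertex, and intermediate 10-10 sites are spherical midpoints of
their flanking 10-20 sites (e.g. FC5 = midpoint of F7 and C3 on the
sphere). Any quantity that depends on geometry — the surface Laplacian
above all — inherits this idealization; with a different head model the
CSD values change, though its qualitative properties (reference-freedom,
spatial sharpening) do not.

## Preprocessing

* **Band-pass** 0.5–48 Hz, order-4 Butterworth applied forward–backward
  (zero phase). The filter family is a design choice; any zero-phase
  band-pass with similar roll-off behaves equivalently downstream because
  coherency is amplitude-normalized per bin.
* **Amplitude rejection** flags whole windows (default: one spectral
  segment, so masks align with the Welch segmentation) containing any
  sample with |x| **strictly** above 100 μV; a sample exactly at the limit
  is kept. Spectral estimation drops every epoch that touches a flagged
  stretch.
* **Artifact correction** is a batch spatial-projection equivalent of the
  interactive topography-preselection approach: epochs around marked
  events are averaged, the averaged segment's spatial PCA components are
  accumulated until ≥ 95% variance (configurable), and the whole recording
  is projected onto their orthogonal complement. Components must also
  exceed 2× the largest singular value of a **sign-alternated** epoch
  average (in which a time-locked artifact cancels but noise survives);
  without that floor, event lists that carry no consistent topography
  would cause noise directions to be projected out. The RRMSE
  RMS(X−X̂)/RMS(X)·100% between original and corrected data quantifies
  how much the correction changed. Event times are supplied (ground truth
  in simulation, user markings otherwise); no automatic artifact search is
  attempted.
* **Surface Laplacian / CSD**: Perrin-style spherical splines, flexibility
  m = 4, 50 Legendre terms, regularization λ = 1e−5, after conversion to
  average reference (the CSD output is reference-free regardless). The
  operator is a fixed matrix per montage, so it commutes exactly with
  channel-wise temporal filtering. The implementation agrees with mne's
  spherical-spline CSD to ~1e−12 up to the analytic unit factor (tested).
  Output units are nominal (μV per squared radian on the unit sphere).

## Connectivity

Cross-spectra use Welch segmentation with a Hanning taper, 50% overlap and
δf = fs/n_FFT = 0.5 Hz (n_FFT = 512 at the synthetic default fs = 256 Hz;
4096 at 2048 Hz). Band edges are half-open [lo, hi) — delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30, gamma 30–48 Hz — and PSI sums only bin pairs
(f, f+δf) lying fully inside the band, so bands never share a bin.

**Jackknife unit.** Segments are grouped into disjoint *epochs* of 2
half-overlapped segments; segments never straddle an epoch boundary. The
raw PSI is computed on the fully pooled coherency; the jackknife leaves
out one epoch at a time and the (B−1)/B-scaled standard deviation of the
replicates normalizes the pooled value. Epochs — not single segments —
are the resampling unit because overlapping segments share samples: a
delete-one-segment jackknife underestimates the standard deviation and
the |Ψ| > 2 threshold then rejects too often (measured ~9% instead of the
nominal 5% on zero-lag mixtures). With disjoint epochs the measured null
exceedance is ~5–6.5% across seed sets, i.e. the threshold's advertised
two-tailed 5% interpretation holds empirically. Under fully independent
channels (no mixing at all) the rate is conservative (<1%): the
calibration statement concerns the volume-conduction null the index is
designed for.

Thresholding keeps entries Ψ_ij > 2 at their original value; skew-symmetry
guarantees at most one direction per pair, hence ≤ (N²−N)/2 = 406 edges.

## Graph metrics

Conventions: A[i,j] is the weight of edge i→j; k_in/k_out are column/row
sums; DI = k_out − k_in. For clustering and local efficiency, weights are
normalized by the matrix maximum and the triangle term uses cube-rooted
symmetrized weights ((W^{1/3} + (Wᵀ)^{1/3})³ diagonal, halved); the
denominators use **binary** degrees, d(d−1) − 2d_recip, so both reduce to
the classic binary directed forms on 0/1 graphs (a binary directed
3-cycle has C_i = 0.5). The local-efficiency prefactor ambiguity (½N vs
mean of node values) is resolved as the mean over nodes of per-node local
efficiencies with the ½ pair-symmetrization; a complete binary digraph
then has LE = 1. Path-based metrics map weights to lengths 1/weight
(after max-normalization, so distances ≥ 1); unreachable ordered pairs
are excluded from the characteristic path length (and counted in the
output) and contribute zero to global efficiency. Betweenness counts
shortest-path multiplicities and is normalized by (N−1)(N−2); shortest
paths and betweenness run on scipy/networkx, while the directed-weighted
clustering and local-efficiency forms are implemented here (no library
provides them) and verified against brute-force enumeration.

**Hub score**: one point each for membership in the lowest-20% clustering,
lowest-20% nodal path length (mean finite out-distance), highest-20%
total degree, highest-20% betweenness; set size ceil(0.2·N) (6 of 29),
ties at the cutoff all included; HS ≥ 2 ⇒ hub. A criterion whose metric
is constant (or undefined) across nodes carries no information and is
skipped with a warning; nodes with undefined values never win a
criterion.

## Statistics

Paired t (two-tailed, df = n−1) on pre/post SAM scores per group. One-way
MANOVA from the E/H SSCP matrices: Λ = det(E)/det(E+H), Rao's F
approximation, partial η² = 1 − Λ^{1/s} with s = min(p, g−1); verified
against statsmodels to 1e−6. Tukey HSD via the studentized-range
distribution with harmonic-mean group size (verified against statsmodels).
Pearson correlations between nodal metrics and outcomes are reported with
uncorrected p-values — the selection rule is an explicit
(band, metric, outcome) list, defaulting to CC/BC in theta and alpha and
LE in alpha against the outcomes showing group effects — plus a clearly
labeled Benjamini–Hochberg column that is *not* part of that rule.
Degrees of freedom are always derived from the data actually supplied,
never assumed.

Hemisphere flow compares mean |Ψ| for eight anterior–posterior pairs
(FP1/2 against F3/4, FC1/2, FC5/6, C3/4, CP1/2, CP5/6, P3/4, O1/2), left
vs right; the signed display convention is positive = anterior →
posterior.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not scalp biophysics:

* **Sources**: white noise filtered into a band (order-4 zero-phase
  Butterworth), unit variance, scaled to a noise s.d. of 10 μV.
* **Couplings**: receiver += strength × sender-source delayed by τ
  (rounded to samples); the topology during the learning condition is
  anterior → posterior (F3→P3, F4→P4 in theta; Fp1→P3, Fp2→P4 in alpha),
  with lags 25–30 ms.
* **Mixing**: identity plus symmetric leakage decaying with
  inter-electrode angle (gain 0.1) stands in for volume conduction.
* **Artifacts**: raised-cosine blink transients (400 ms) with a fixed
  frontal-weighted topography at Poisson times.
* **Behavior**: Gaussian draws around group means, truncated/rounded into
  valid ranges (SAM integers 1–9, ACC 0–100%, RT > 200 ms).

Defaults are the study conditions: three groups (achromatic GB&W,
cool-colored CCI, warm-colored WCI), 14 subjects per group. SAM change
means come from the published pre/post group means (valence +2.57 and
arousal +1.79 for WCI, valence +2.36 and arousal +0.9 for CCI, 0 for
GB&W); the within-subject change s.d. (1.34) is back-derived from the
reported paired t statistic at n = 14. Behavioral group means are free
parameters (only F statistics are published) chosen to give effect sizes
of the same order: RT₁ 3000/3100/2400 ms, ACC₂ 55/67/55% (s.d. 550 ms /
10%). Learning-condition coupling strengths are 0.25/0.5/0.65
(GB&W/CCI/WCI) vs 0.15 at rest, and each subject's strength is further
modulated by +0.12 per z-unit of their arousal change — this injects a
metric–outcome dependence of known (positive) sign between receiver
in-strength and arousal, which the correlation layer must recover.
Recordings default to 30 s at 256 Hz (≈ 10 jackknife epochs), a
desk-scale choice that keeps Monte-Carlo suites fast while leaving the
estimator's segment economy realistic; the fs = 2048 Hz acquisition case
is covered by the structural resolution check rather than by bulk
simulation.

What the generator does **not** model — 1/f background spectra, true
cortical source geometry, EOG/ECG waveform families, nonstationarity,
inter-subject montage variation — bounds what passing tests show: they
validate the estimators and the pipeline logic under the stated
assumptions, not performance on real scalp data.

## Numerical notes and degenerate inputs

Zero-power spectral bins yield undefined coherency and are excluded.
A zero jackknife s.d. (e.g. duplicated channels, pure tones) raises
rather than returning infinities; entries with zero s.d. but nonzero
others are set to 0. Graph metrics require a zero diagonal and
non-negative weights; empty graphs return 0 for clustering/efficiencies
and NaN (with a count of unreachable pairs) for the characteristic path
length. The pipeline is a pure function of (dataset, config, seed):
reruns are byte-identical, which the suite asserts.

## Limitations

PSI cannot distinguish direct from mediated influence, gives no coupling
magnitude in physical units, and assumes an approximately linear phase
within the band. The |Ψ| > 2 threshold is per-pair, uncorrected for the
406 simultaneous pairs — matching the analysis it reproduces, not
state-of-the-art network inference. The hub-score quantile rule is
montage-size dependent and tie-sensitive on sparse graphs. The surface
Laplacian depends on idealized geometry (above). Group statistics are
classical parametric tests; no mixed-effects or permutation alternatives
are provided.
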