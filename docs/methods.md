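# Methods

This note documents the models, numerical choices and limitations behind
`sourcetf`. It is written for users who want to know exactly what the
package computes and what the synthetic validation does — and does not —
demonstrate about real recordings.

## Problem setting

Event-related EEG dynamics decompose into two distinct phenomena: changes
in band-limited oscillatory *power* relative to a pre-stimulus baseline
(event-related desynchronization, ERD, and synchronization, ERS — together
the event-related spectral perturbation, ERSP), and changes in the
*consistency of oscillatory phase* across trials (inter-trial coherence,
ITC). The package estimates both in source space: the per-trial sensor
signals are band-limited, turned into complex analytic signals, mapped into
a voxel grid by a linear inverse operator, reduced to per-voxel ERSP and
ITC maps over configured band/time windows, and compared across subjects
and conditions with a permutation-corrected paired t test.

## Forward model

The head is a homogeneous conducting sphere (default radius 90 mm,
conductivity 0.33 S/m) with an insulating exterior. For a current dipole
with moment **m** at position **r**₀, the surface potential at electrode
**r** is the classical closed form

V(**r**) = (4πσR)⁻¹ **m**·[ 2R(**r**−**r**₀)/d³ + (**r** + R(**r**−**r**₀)/d)/F ],

with d = |**r**−**r**₀| and F = R² − **r**₀·**r** + Rd, which is the summed
Legendre series of the Neumann Green's function (the test suite checks the
implementation against a truncated-series oracle to < 0.1 %). Electrodes
are projected radially onto the surface; the default montage is a
deterministic Fibonacci-lattice cap of 128 electrodes covering polar angles
to 120°. Source spaces are regular origin-aligned grids (x fastest) inside
sphere/box/ellipsoid masks, with free 3-component orientation per voxel.
Gains are µV per nA·m.

A single homogeneous sphere is a deliberate simplification: it has no
skull/scalp conductivity profile, so its depth-sensitivity fall-off differs
from a realistic boundary-element model. Validation against ground truth
therefore always uses the sphere's own gains; externally computed gain
matrices (e.g. BEM) can be injected through `load_leadfield` and flow
through every downstream stage unchanged.

## Inverse: depth-weighted standardized minimum norm (swLORETA)

Let L be the M×3V lead field, H = I − (1/M)𝟙𝟙ᵀ the average-reference
projector, and L̄ = HL. Per voxel, the depth weight is
ω_v = s₁(G_v)^(−γ) with s₁ the largest singular value of the voxel's M×3
gain block; γ = 1 by default, γ = 0 recovering plain sLORETA. With
W = blockdiag(ω_v I₃),

T = W L̄ᵀ (L̄ W L̄ᵀ + λH)⁺,  S_v = [T (L̄ W L̄ᵀ + λH) Tᵀ]_vv,

and the standardized power of an estimate ĵ_v = (T x)_v is
q_v = ĵ_vᴴ S_v⁺ ĵ_v. Pseudoinverses are used throughout because
average-referenced operators have rank M−1; all PSD pseudoinverses use a
relative eigenvalue tolerance of 10⁻¹².

Choices where the design was open:

* **Weighting family.** The exact SVD-based weighting of the original
  swLORETA formulation is not uniquely pinned down in the literature we
  implement from; we adopt the one-parameter family ω_v = s₁^(−γ), which
  reproduces the intent (compensate sensitivity decay with depth), is
  documented, and degrades gracefully to sLORETA at γ = 0.
* **Regularization.** λ = trace(L̄WL̄ᵀ)/(M·SNR²) with SNR = 3 by default —
  the standard scaling-invariant rule under a white-noise assumption with
  noise covariance ∝ H.
* **Scale behaviour.** Rescaling the lead field together with the data
  (x = Lg → cLg) leaves the standardized map exactly invariant at γ = 0; at
  γ > 0 the whole map scales by one global factor, so localization, map
  shape and paired-t inference are unaffected. This is why the package
  reports standardized power in arbitrary units.
* **Per-trial application.** The operator is data-independent, so one
  operator per montage/geometry is built and reused across all trials and
  subjects; complex analytic signals pass through the same real transfer
  matrix component-wise.

With λ → 0 and noiseless single-dipole data the standardized-power argmax
is provably at the true voxel (sLORETA's exact-localization property, which
survives the diagonal weighting); the acceptance suite verifies this
exhaustively on a 6×6×6 interior grid.

## Analytic signals and source ERSP / ITC

Band-limiting and the Hilbert transform are performed in one step: epochs
are reflection-padded to three times their length, transformed, multiplied
by a one-sided raised-cosine band response (2 in the passband, 0 for
f ≤ 0), and trimmed. Transition widths are
min(f_lo, (f_hi−f_lo)/2, 2 Hz) below and min((f_hi−f_lo)/2, 2 Hz) above the
band. This is zero-phase by construction — important because ITC latencies
must not be distorted — and behaves well for very low bands (0.2–2 Hz) on
4-s epochs where a windowed-sinc kernel of the required length would exceed
the epoch. Bands must satisfy bandwidth × duration ≥ 2 cycles. Amplitude
estimates are accurate to ~2 % away from the padded edges; analyses should
keep windows of interest a few hundred ms inside the epoch.

**ERSP.** Per trial n and voxel v, p_{n,v}(t) = q(ĵ from the analytic
signal). The map is the trial average minus its own mean over the baseline
window (−850 to −50 ms by default) — the additive baseline model, so ERD is
negative, ERS positive, and a stationary process gives ≈ 0 everywhere.
Values are raw standardized-power differences (arbitrary units), not dB.

**ITC.** The 3-component complex estimate is collapsed to a scalar per
voxel before phase is taken; a whole-vector normalization would mix
orientation changes into the phase statistic. Default collapse: projection
onto the dominant eigenvector of the voxel's trial-stacked cross-spectral
matrix (fixed per voxel and band); the max-mean-power component is
available as an alternative and agrees with the default on strong sources.
ITC_v(t) = |(1/n)Σ_n h/|h|| ∈ [0,1]; zero-amplitude samples are excluded
with count adjustment, and voxels with no valid samples are flagged NaN
rather than silently 0. Window averages use half-open [t_lo, t_hi)
intervals.

The default band/window table has six cells — ERSP: 3–5 Hz at 750–1150 ms,
9–13 Hz at 530–750 ms, 9–17 Hz at 1000–1350 ms; ITC: 0.2–2 Hz at
225–425 ms, 4–7 Hz at 480–520 ms, 10–12 Hz at 480–520 ms — and is fully
configurable.

## Group inference

Subject-level contrasts are paired differences of window maps (condition A
vs B, or a window vs the baseline window of the same measure). Voxelwise
t = mean/(sd/√S); zero-variance voxels get t = 0, are flagged and are
excluded from the maximal statistic. The family-wise error over voxels is
controlled by sign-flip permutation of the subject differences: the null
distribution of max_v |t| (two-sided default, since both ERD and ERS are
expected) is built from all 2^S sign patterns when 2^S ≤ 4096 (S = 11
subjects → 2048, complete enumeration) or from Monte-Carlo flips including
the identity otherwise. The corrected threshold is the 95th percentile of
that null under the step-CDF ("higher") quantile convention — the smallest
null value whose CDF reaches 0.95 — which keeps the test at or below the
nominal 0.05 level and makes Monte-Carlo and enumeration thresholds agree
on discrete nulls. Sign flipping (rather than label shuffling) matches the
exchangeability structure of paired differences.

The package ships a calibration harness (`fwer_calibration`): on i.i.d.
standard-normal global-null datasets the long-run probability of any false
positive is ≈ 0.049 at 1024 flips (measured at 2000 datasets); individual
200-dataset estimates scatter binomially around that value.

## Synthetic data generator

The generator emulates a two-condition, multi-subject visual-cue study:
128 channels, 512 Hz, epochs −1 to 3 s, 11 subjects, 90 trials per
condition by default (tests and the demo use smaller geometries — fewer
channels, 128–256 Hz, coarser grids, 12–40 trials — chosen so each check
isolates one property at a readable effect size).

Each dipolar source oscillates at its centre frequency with a fresh
uniform phase per trial. Two event-related mechanisms are available, built
to be orthogonal so ERSP and ITC can be validated independently:

* **ERD/ERS** — the amplitude steps by gain g inside the modulation window
  (band power changes by g², phases stay uniform, ITC stays at chance);
* **phase reset** — at the reset latency the phase is redrawn from a von
  Mises(0, κ) distribution (expected ITC = I₁(κ)/I₀(κ), expected power
  unchanged).

Modulation windows and reset latencies must stay ≥ 2 cycles from the epoch
edges (validated). Between-subject variability is a multiplicative
lognormal jitter (sd 0.2 by default) on g and κ, which is what makes the
paired t across subjects meaningful. The background is a configurable
number of pink-noise (1/f) dipoles at random voxels — amplitude 10, 30
dipoles by default — plus white sensor noise (2 µV RMS by default, a
mid-range value for high-density recordings). Sources are snapped to the
nearest grid voxel so ground-truth voxel indices are exact.

What the generator does **not** emulate: ocular/muscle artifacts, head
movement, electrode drift, 1/f aperiodic exponent variation, correlated
multi-source networks, or realistic skull conductivity (see forward
model). Passing the validation suite therefore demonstrates correctness of
the estimators and calibration of the statistics under the stated model —
not robustness to every property of real recordings.

## Preprocessing

Zero-phase FIR throughout (odd-length windowed-sinc kernels, applied
forward-backward). Default chain: 200 Hz low-pass at the native rate,
polyphase resampling to 512 Hz, optional 47.5–52.5 Hz notch, then the
high-pass (0.1 Hz) at the target rate. The high-pass kernel is built by
spectral inversion of a unit-DC-gain low-pass, so DC is nulled exactly even
when the kernel must be capped (at a quarter of the record length) for
short records. Epochs are half-open windows with per-epoch, per-channel
baseline subtraction.

Automatic epoch rejection mirrors visual screening: an epoch is dropped if
any channel exceeds ±100 µV, or if any channel's band log-power deviates
from that channel's grand-average log spectrum beyond the configured bounds
— [−50, +50] dB for 0.1–2 Hz, and the asymmetric [−100, +5] dB for
20–40 Hz (large broadband-high-frequency increases are muscle-artifact
suspects; decreases are tolerated). Deviations are evaluated per channel,
the stricter of the two natural readings; both bands and bounds are
configurable.

## Problem sizes and determinism

Validation runs use deliberately small geometries (32–64 channels, 16–25 mm
grids, 10–400 trials) so each property is measured in seconds while
remaining statistically decisive; all sizes are configurable upward. Every
stochastic step takes an explicit seed; the pipeline derives all stage
seeds from one configuration seed via `numpy.random.SeedSequence`, and a
rerun with the same configuration is byte-identical. Degenerate inputs
(zero gain blocks, zero-variance voxels, zero-amplitude analytic samples,
empty windows, empty grids) are rejected or flagged explicitly rather than
propagated as silent zeros.

## Known limitations

* The homogeneous sphere overestimates deep-source sensitivity relative to
  a realistic three-compartment head; claims about deep (thalamic,
  cerebellar) generators in real data need a realistic lead field supplied
  via the loader.
* Grid coordinates are reported in the model's own mm frame; no atlas
  registration or anatomical labeling is performed.
* ERSP/ITC are computed per configured band/window cell, not as full
  continuous time-frequency decompositions.
* The permutation test assumes subject exchangeability under sign flips of
  paired differences; it does not model within-subject trial-count
  imbalance.
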