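# Methods

This note documents the models, estimators, numerical choices and known
limitations of `ictalnet`, in the spirit of a methods appendix. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Forward model

The head is five concentric homogeneous spheres (white matter, gray matter,
CSF, skull, scalp). Default radii are (71, 78, 81, 85, 92) mm — common
adult-template proportions, configurable — with conductivities
(0.31, 0.33, 0.33, 0.0042, 0.33) S/m. All shells are isotropic; an
`anisotropy_ratio` knob exists but only the isotropic value 1.0 is
implemented, because a scalar conductivity per shell cannot express a
radial/tangential split unambiguously.

For a dipole at radius `b` (normalized to the scalp radius) the potential is
a Legendre series; per degree `n` the radial dependence through the shell
stack is solved with 2×2 transfer matrices (continuity of potential and of
radial current at each interface; zero radial current at the scalp). The
series is truncated adaptively when the relative change of the partial sums
falls below `tol` (default 1e-8) with a hard cap of 200 terms, which bounds
the runtime for superficial dipoles. Lead fields are average-referenced;
column sums vanish to ~1e-13 relative.

Two independent oracles check the solver: (i) with equal conductivities it
matches a closed-form homogeneous-sphere dipole potential (derived by
summing the series with generating functions) to better than 1e-6 relative;
(ii) the per-degree radial gains match a fine finite-difference solution of
the radial conduction ODE to ~1e-4.

The source grid contains every point of a cubic lattice (default 5 mm)
strictly inside the innermost shell with a one-voxel margin (~9 800 nodes).
Electrode montages (19/32/38/50/64 channels) take their directions from the
standard 10-05 position table shipped with MNE-Python, projected radially
onto the scalp sphere around a least-squares sphere fit.

## Synthetic ictal EEG

Sources are damped AR(2) resonators at the centre of the analysis band
(pole radius `1 − πΔf/fs`, so the −3 dB width matches the band width),
embedded in a VAR(5). A directed edge j → i adds taps `c·(1, −0.5, −0.5)`
at lags 1–3 of source j to the update of source i, scaled by the inverse of
the resonator gain and of the raw tap gain at the band centre, so that the
edge ``strength`` is its resonant loop gain. This makes stability
transparent: a directed ring is stable iff the product of its strengths is
below one, at any sampling rate. (With taps interpreted naively as AR
coefficients, any ring of resonators is violently unstable — companion
radius ≈ 1.3 at strength 0.5 — because the resonator gain at the band centre
multiplies the loop.) An explicitly unstable graph is rejected with the
companion spectral radius in the message.

Defaults, chosen once as a plausible ictal regime: coupling strength 0.7
(per-frequency driven coherence c²/(1+c²) ≈ 1/3 at resonance — strong but
not deterministic synchrony), band 16–20 Hz, sampling rate 200 Hz (the
recording hardware this emulates runs at 2 kHz; the generator is
rate-agnostic and everything takes `fs` as a parameter), sensor SNR 5 dB
(the validation studies use 10 dB where they say so). Three template source
positions 49–95 mm apart, snapped to grid nodes so that localization error
has an exact zero. In the star ("onset") preset the primary source has twice
the innovation amplitude: the seizure-onset zone is the strongest source,
which is also what lets the power map identify the primary. Sensor noise is
Gaussian, white in time and across channels (a spatially correlated option
exists, default off). Scalp data are average-referenced microvolts.

What the generator does **not** emulate: epileptiform waveform morphology
(spikes, sharp waves), background rhythms, 1/f noise, artifacts, volume
conduction beyond the spherical model, or nonstationary amplitude dynamics.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis chain*, not clinical performance on patient EEG.

`make_ictal_recording` concatenates a pre-ictal baseline (noise only), an
onset phase with the star coupling graph and a middle phase with the ring
graph, with continuous sensor noise; the regime switch defaults to the
seizure midpoint and is configurable (`middle_start`). The CLI preset
switches 10 s after onset so the mid-seizure analysis window contains only
mid-seizure dynamics. Ground truth is stored in a JSON annotation that
round-trips bit-identically.

## Segments, band, cross-spectra

Sample windows are half-open with floor rounding: the onset window is
`[t_on − 5 s, t_on + 5 s)`, the middle window 10 s centred on the seizure
midpoint; both shrink to 1 s for seizures shorter than 3 s, and a short
seizure's middle window slides right to abut the onset window instead of
overlapping it (for long seizures an overlap is an error). The analysis band
is the frequency of maximal global field power — the across-channel sum of
Welch power spectra of the average-referenced segment, searched in
0.5–45 Hz — ± 2 Hz. Cross-spectral densities are Hann-tapered Welch
estimates (1 s windows, 50 % overlap), Hermitian by construction, with the
convention `S_ab = X_a · conj(X_b)`.

## DICS beamforming

Spatial filters are unit-gain LCMV filters computed from the real part of
the band-averaged CSD with diagonal regularization `α · mean(diag)`,
α = 0.001 (dimensionless because of the mean-power scaling). The dominant
orientation per node is the leading eigenvector of the 3×3 real output
matrix; the power map is the largest eigenvalue of `A C Aᴴ` on the complex
CSD. Raw beamformer power has a strong depth profile on pure noise
(‖w‖² grows for deep voxels, max/median ≈ 12); the noise-normalized map
(power/‖w‖²) is flat to within a factor 1.5 on source-free recordings.

**Coherence maps.** Per voxel, the magnitude-squared coherence between the
beamformed voxel signal and the reference source signal is computed per
frequency bin and averaged across the band. Averaging the complex CSD over
the band first would cancel genuine coherence, because the cross-spectral
phase of lag-coupled resonators rotates rapidly across a resonance. The
reference is "projected out" with the oblique operator `P = I − l wᵀ/(wᵀl)`
(topography `l`, reduced filter `w`): applied on the voxel side it removes
exactly the deterministic beamformer leakage of the reference from every
voxel's series, so the reference and its leakage halo drop to zero while
genuine coherence carried by other dipoles survives; Cauchy–Schwarz keeps
the values in [0, 1]. The map is blanked within two voxels of the reference:
after the reference dipole is removed, the residual at that location is
leakage of *other* coherent activity and says nothing about a source there.
Statistical partialization on the reference signal (subtracting
`c_r c_rᴴ/s_rr` from the CSD) is *not* used: it annihilates every
cross-spectrum with the reference identically, including the dependence the
map is supposed to image.

**Network search.** The power-map maximum is the primary source (no
significance gate — the strongest source defines the reference region).
Subsequent candidates come from a projected subspace-correlation scan of the
residual CSD: with the accepted sources' lead-field subspaces removed
(orthogonal signal-space projection — exact for any dipole orientation, no
noise amplification), the candidate is the node whose projected lead field
best correlates with the dominant residual signal subspace. This sequential
scan recovers the remaining sources exactly in the validation studies,
whereas the coherence-map argmax is ill-posed with two or more coherent
partners: coherence is scale invariant, so voxels whose leakage mixes two
partners can outscore the true sources. Each candidate is accepted if its
coherence with any accepted source exceeds the per-voxel 99th percentile of
a *reference-permutation* null — the reference source's (non-overlapping)
analysis windows are permuted against the intact voxel signals, which
destroys exactly the dependence under test while preserving the narrowband
spectra and the spatial structure of the data. The number of iterations is
capped by the coherent-subspace dimension: the number of band-CSD
eigenvalues above 10× the median eigenvalue (in the study conditions true
sources sit at ≥ 100×, the noise floor below 2×). Accepted nodes are kept
at least 4 voxels (20 mm) apart. A primary without any significant coherent
partner is flagged weak, which is what a baseline (source-free) recording
produces.

**Why the sensor-shuffle surrogate is kept but not used as the detection
gate.** The literal surrogate — shuffle 1 s windows independently per
channel, recompute the map, take the per-voxel 99th percentile of (default)
100 permutations — is implemented as `surrogate_threshold` and is exactly
calibrated on unstructured data: on source-free noise the observed power map
exceeds the threshold at 0 % of voxels (conservative under average
reference). But for structured narrowband recordings this null is unusable
as a detection test: shuffling destroys the spatial covariance structure
that lets the minimum-variance filter suppress output power, so surrogate
beamformer power exceeds the observed power *everywhere* — a true focal
source can never pass, and surrogate coherence maps are likewise inflated.
The reference-permutation null above is the matched replacement for the
coherence stage.

## Source extraction and directionality

Source series for the connectivity stage are extracted with jointly
constrained minimum-variance weights: unit gain on each node's topography
and explicit nulls on the *neighbourhood* lead-field subspaces (dominant 8
singular directions of the node and its grid neighbours) of the other
accepted nodes, so cross-talk stays suppressed even when a node is off the
true source by a voxel. Cross-talk is the dominant failure mode of directed
measures on beamformed signals: a driven series containing a clean leaked
copy of the driver's past produces strong *reverse* apparent causality.

Extraction is broadband. Band-pass filtering before autoregressive modelling
— especially zero-phase filtering — erases the lagged structure that
directed-influence measures rest on (measured: forward RPDC drops three
orders of magnitude after zero-phase band-passing). Instead, the extracted
series are causally decimated so that the analysis band sits near the new
Nyquist frequency (`decimate_for_band`, default headroom 2.5, e.g.
200 Hz → 50 Hz for a 16–20 Hz band). The same minimum-phase anti-alias
filter is applied to every series, which leaves directed structure
invariant, while concentrating the modelled bandwidth on the band:
broadband sensor noise on a narrowband signal otherwise biases the VAR
cross terms (the signal-plus-noise process is VARMA, not finite VAR).

The MVAR is fitted by least squares via QR on the lagged design (verified
against an independent implementation to machine precision), the order
selected by AIC `n·log det Σ̂ + 2m²p` with a default cap of `p_max = 10` on
the decimated series — past that, the extra parameters visibly scramble the
direction estimates. RPDC is
`λ_{j→i}(f) = Zᵀ V(f)⁻¹ Z` with `Z = (Re Ā_ij(f), Im Ā_ij(f))` and `V` the
asymptotic covariance of `√n Z`, propagated from the coefficient covariance
`Σ ⊗ (XᵀX)⁻¹` through the Fourier map; under the null `n·λ` is χ²(2)
(measured mean ≈ 1.98 over 200 null fits), and λ is invariant to rescaling
individual series (PDC is not). Singular 2×2 renormalization matrices fall
back to the pseudo-inverse with a warning.

Significance uses the 19-shuffle bootstrap (1 s windows, independent per
series; the observed estimate is the 20th). Two decision rules ship:
the literal "observed > surrogate mean" rule — whose false-positive rate
under the null is ≈ ½ per pair, by symmetry; measured 0.3–0.7 — and the
rank rule "observed > surrogate maximum", an exact p = 1/20 test. The
pipeline classifies with the rank rule. Two further guards reflect source
leakage: significant edges below 0.4× the strongest edge are treated as
leakage pseudo-edges and dropped (in the generator's calibration studies
genuine edges sit above ~0.55× the dominant edge and artifacts below ~0.35×),
and nodes participating in no retained edge are removed before
classification (a region without flow is not part of the flow pattern).

Flow patterns: `star_out` iff every edge originates at the primary and every
other node receives one; `circular` iff the digraph contains a directed
cycle through ≥ 3 nodes; otherwise `mixed`; `empty` without edges.
Directionality is refused for segments shorter than 3 s unless forced,
mirroring the exclusion of very short seizures from directional analysis.

## Pipeline, determinism, problem sizes

`analyze_phase` chains segment → band → CSD → network → extraction →
MVAR/RPDC → classification; `run_phase` adds artifact files (JSON reports
with config hash and seed, NIfTI/CSV maps, tidy RPDC CSV, GraphML, SVG bar
plots whose dashed lines mark the bootstrap significance level);
`compare_phases` matches nodes within two voxels and contrasts the edge sets
and topologies. All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; re-running with the same seed reproduces every
map, threshold and report bit-identically. Analyses never read the
generator's ground-truth annotation (blinded by construction); the
annotation is only consulted afterwards, by tests and comparisons.

Validation studies run at deliberately modest sizes — 32 electrodes,
200 Hz, 5 mm grid (~9 800 voxels), 10 s segments for localization, 60 s for
coherence recovery and flow classification, 20 permutations in the search
(100 in the calibration study), 20 seeds per rate — chosen so the whole
suite re-runs in minutes on one CPU while leaving wide margins to the
thresholds they are checked against.

## Known limitations

- Ten-second mid-seizure windows are at the edge of what the rank-rule
  bootstrap can certify for ring edges at the default effect sizes: the full
  `circular` label is recovered reliably from ~60 s of data (the method
  genuinely needs long segments), but 10 s windows often yield a partial
  ring (`mixed`).
- The eigenvalue-based source count assumes sources well above the sensor
  noise floor in the analysis band; weak deep sources below 10× the median
  eigenvalue are not searched for.
- The surrogate-mean significance rule is reported for completeness but is
  far too permissive for classification; results based on it should be read
  as descriptive.
- The spherical head model, white noise, and stationary VAR sources are
  idealizations; none of the validation rates transfer to patient data
  without a realistic head model and artifact handling.
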