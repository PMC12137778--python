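# Methods

## Signal model

The simulator treats each material as a binary spin bath: a free water pool
with longitudinal/transverse relaxation times T1f, T2f (ms) and a
macromolecular bound pool holding a fraction f of the total equilibrium
magnetization, with longitudinal relaxation T1b (ms) and a microsecond-scale
transverse lifetime T2b (μs) that makes it directly invisible but RF
saturable. Exchange follows detailed balance with fundamental rate k (s⁻¹):
forward rate k·f, reverse k·(1−f), so that k·f·M0f = k·(1−f)·M0b at
equilibrium. f = 0 reduces exactly to a single-pool simulation.

### Pulse model and bound-pool saturation

RF pulses are hard (rectangular), width τ (μs), flip angle α (degrees;
values up to 420° are allowed, and a rotation by α is identical to one by
α − 360°). The free-pool rotation is treated as instantaneous at the pulse
center, so free-pool relaxation runs over the full TR between rotations;
this makes the single-pool signal exactly independent of τ, which is the
control condition the pulse-width experiment relies on. The bound pool sees
the full pulse: mean amplitude ω₁ = α_rad/τ, saturation rate
W = π ω₁² G(0), per-TR attenuation exp(−W τ).

G(0) is the absorption lineshape on resonance. The default is Gaussian,
G(0) = T2b/√(2π). The super-Lorentzian lineshape diverges on resonance, so
when selected it is evaluated at a 1 kHz cutoff offset
(`SUPER_LORENTZIAN_CUTOFF_HZ`, configurable), the standard regularization in
quantitative-MT work. The lineshape of the phantom materials is not known at
64 mT; Gaussian is the default because it is well-posed on resonance.

### EPG engine

The free pool is propagated in configuration space (F_k for k = −K..K, Z_k
for k = 0..K; K = 40 by default, with truncation error testable by doubling
K). One TR applies, in order: bound-pool saturation; RF mixing of each
(F_k, F_−k*, Z_k) triple by the standard unitary rotation matrix (the bound
pool has no transverse magnetization and is not rotated); relaxation and
exchange over TR; one configuration-order shift of the transverse states by
the ideal spoiler (no diffusion damping). The FID observable is |F₀| after
the pulse; the echo observable is the F₋₁ pathway sampled immediately
before the next pulse (its exact timing within TR is a free choice of the
implementation; sampling at the end of TR is the convention used
throughout).

Longitudinal propagation is exact: the coupled pair (Z_k, Zb_k) evolves by
the matrix exponential of the Bloch–McConnell generator, with the recovery
source feeding order k = 0 only. The bound pool is tracked per
configuration order, not as a single scalar: RF mixing makes the free-pool
Mz phase-dependent across the spoiler cycle, and exchange imprints those
harmonics onto the bound pool, which feeds them back. Neglecting the bound
orders biases the two-pool echo by several percent at white-matter-like
parameters; tracking them brings the EPG engine to within numerical
precision of the isochromat oracle.

Steady state is found by fixed-point iteration from thermal equilibrium
(tolerance 1e-10 relative on both observables, cap 10 000 iterations, with
a geometric extrapolation of the remaining distance to the fixed point so
that the reported signals are accurate to the tolerance rather than merely
stationary). The result is independent of the initial state; a
`ConvergenceError` with iteration diagnostics is raised otherwise.

### Isochromat oracle

`isochromat_oracle` is an independent brute-force reference: N isochromats
(default 2000) uniformly sample 2π of spoiler dephasing per TR and evolve
by time-stepped dynamics (16 substeps per TR: incremental precession, T2
decay and the exact longitudinal exchange propagator). With n isochromats
the configuration orders alias with period n, so the agreement with the EPG
engine improves with n and reaches the numerical floor once n exceeds the
retained EPG orders. The acceptance suite checks ≤ 1e-3 relative agreement
over f ∈ {0, 0.05, 0.15} × α ∈ {60°, 180°, 300°}; the observed agreement
is ~1e-12.

### Protocol and field conditions

The default protocol follows the ultra-low-field implementation: TR =
12.03 ms, τ = 220 μs, PSIF (echo) readout, FOV 180×220×200 mm³, voxels
2×2×5 mm³ (matrix 90×110×40), bandwidth 18 kHz (metadata). Transmit error
is a single multiplicative B1 scale on the nominal flip angle: with scale
s, the single-pool signal null sits at nominal angle 180°/s, which
reproduces the experimentally observed offset of the null from 180° to
~190° for s ≈ 0.95.

## Key properties exploited by the analysis

* Single-pool PSIF symmetry: S(α) = S(360° − α), hence MTR = 0 at any
  mirror pair for f = 0 regardless of T1/T2 — the specificity argument.
* The signal null at 180° (ideal B1).
* Asymmetry about the symmetry point grows with f: the asymmetry index
  [S(α*−δ) − S(α*+δ)]/[S(α*−δ) + S(α*+δ)] and MTR at a mirror pair are
  monotone in f with other parameters fixed.

`find_symmetry_point` scores every grid angle by the mean absolute signal
difference over all mirror pairs available on the grid and returns the
minimizer. Because the flip-angle response is periodic in 360°, a sweep
extending past 360° (the 1°–420° experimental grid) is also exactly
symmetric about 360°; ties at numerically zero asymmetry are therefore
broken toward the axis supported by more mirror pairs, then toward the
smaller angle. `choose_flip_angle_pair` enumerates all pairs symmetric
about the no-MT symmetry point, keeps those with matched reference signal
(tolerance `signal_match_tol`, default 0.05 of the maximum) that stay near
the reference peak (`min_signal_frac`, default 0.9), and returns the pair
maximizing the predicted MTR on the MT curve; ties prefer the higher
reference signal, then the smaller low angle. The defaults encode "equal,
near-maximal signal in the no-MT material"; with the peaks of the preset
materials the selected pair is (90°, 270°), while the experimentally
chosen (60°, 300°) is recovered when the reference curve peaks there — the
selection depends on where the actual materials peak, which is why it is
exposed as an operation rather than hard-coded.

## Digital phantoms and acquisition simulation

The phantom generator emulates the bench experiments used to develop the
protocol, not any deposited dataset (none exists):

* **Six-vial MT phantom** — two vials each of water (f = 0), a dairy-cream
  stand-in (moderate f) and a hair-conditioner stand-in (higher f), as
  parallel cylinders in a 90×110×40 grid.
* **Relaxometry array** — up to 14 vials per layer on a circle, arbitrary
  (T1, T2) per vial, f ≡ 0 throughout: the negative control showing that
  T1/T2 variation alone produces no MT contrast.
* **Tissue presets** (`data/presets_64mT.yaml`) — white-matter-like,
  CSF-like, water, cream-like, conditioner-like parameters at 64 mT. These
  are literature-informed estimates chosen once: two-pool parameters of
  these materials at ultra-low field are not tabulated anywhere; free-pool
  T1 values are shortened relative to clinical fields, T2 kept similar, f
  of white matter set to 0.10 with k = 25 s⁻¹ and a reduced bound-pool T1
  (300 ms), consistent with the mechanism that lowers MTR at low field.
  The predicted white-matter MTR at (60°, 300°) with these presets is
  ~19.5%, in the right regime but not a fit to any measured value.

Rasterization assigns a voxel to a compartment iff its center lies inside
the geometry (no partial-volume mixing), so compartment means are exact;
overlaps are rejected. Acquisition simulation computes one steady-state
solve per tissue class (compartments are homogeneous, so a 43-angle sweep
of the full-size phantom costs ~260 solves, seconds of CPU), multiplies by
smooth complex coil sensitivities (Gaussian lobes on the FOV perimeter,
jittered by the seeded generator; strictly positive magnitude) and adds
i.i.d. complex Gaussian noise per receive channel in the image domain —
equivalent to k-space noise for this noise model and deliberately avoiding
a reconstruction chain, which is out of scope. Magnitude images are formed
by root-sum-of-squares, so pure-noise regions follow a noncentral-chi/chi
family with 2·n_coils degrees of freedom (verified against the analytic
mean). All randomness flows from one seeded generator recorded in the
provenance sidecar; identical configuration and seed reproduce outputs bit
for bit.

What the synthetic data does **not** emulate: compressed-sensing
reconstruction artifacts, gradient-nonlinearity distortion, motion and
flow, B0 inhomogeneity banding, partial voluming, or spatially varying B1.
Passing tests therefore demonstrate the correctness of the signal model
and analysis chain under the stated noise model, not in vivo image
quality; in vivo headline values (white-matter MTR, scan–rescan CoV of a
specific cohort) depend on scanner data and tissue parameters that are not
public and are deliberately not claimed.

## MTR analysis

`compute_mtr_map` applies MTR = (low − high)/low × 100 on voxels whose
MT_low intensity exceeds a validity threshold (default 5 × a background-SD
estimate from the volume's corner patches; the high-flip image is often
near the noise floor, and low MT_low voxels would otherwise produce wild
ratios). Invalid voxels are NaN, never zero; values are not clipped, so
noise-driven negative MTR remains visible in histograms. ROI statistics
use the sample SD (n − 1) throughout — required for the two-scan CoV bias
factor 1 + 1/(4n) = 1.125 at n = 2 — and report empty ROIs as explicitly
missing. Histograms use bin edges at integer multiples of the bin width
covering the data, so counts are conserved under bin-width changes.
Bland–Altman limits are bias ± 1.96 × SD of the paired differences.
Non-local-means denoising (scikit-image) is optional and off in all
quantitative tests, since it trades variance for spatial bias.

## Numerical choices and limitations

* Degrees/ms/μs at interfaces, radians/seconds internally.
* Grid ties (argmin/argmax, pair selection) break toward the smaller angle.
* K = 40 EPG orders: truncation error < 1e-6 relative at tissue-like T2/TR
  (verified by doubling K); very long T2 with α near 180° converges more
  slowly but remains protected by the exact mirror symmetry of the update.
* The pulse-width grid 40–220 μs in 20 μs steps has 10 points; the bench
  description of the corresponding experiment counts 11 acquisitions,
  which does not match the stated grid and is not reproduced.
* The relaxometry-array T1/T2 values are user-supplied (the reference
  hardware's values are not machine-readable); the defaults span
  35–2000 ms in T1 and 11–1000 ms in T2.
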