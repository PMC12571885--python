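# Methods

This note documents the models and numerical conventions behind `irmd`:
what each stage computes, which parameters matter, what the synthetic
oracle does and does not emulate, and where design choices were genuinely
open.

## Units

Internal units are Å, fs, eV, amu, elementary charge and Debye; spectra
are on a wavenumber (cm⁻¹) axis. All conversion factors derive once from
SI/CODATA definitions in `irmd.units`: force→acceleration
(eV·Å⁻¹·amu⁻¹ → Å/fs², ≈ 9.6485 × 10⁻³), e·Å → Debye (≈ 4.8032), and
ν̃ = ω/(2πc). A useful anchor: a bond of curvature 1 eV/Å² between two
1 amu atoms vibrates at 737.47 cm⁻¹.

## The analytic oracle

The oracle replaces an electronic-structure labeller with a bonded force
field whose energies, forces and dipoles are exact and cheap:

    E = Σ_bonds V(r) + Σ_angles ½ k_θ (θ − θ0)²,
    V_morse(r) = D_e (1 − e^{−a(r−r0)})²,   V_harm(r) = ½ k (r − r0)².

Morse bonds are the default because anharmonicity is the very property
MD-based spectra add over the harmonic approximation; harmonic bonds are
kept for closed-form tests. The dipole surface is fixed point charges
referenced to the centre of mass, μ = Σ qᵢ(rᵢ − R_COM).

Generated surrogates draw bond stiffnesses k ∈ [15, 45] eV/Å² (typical
single-bond stretch curvatures: a C–H bond near 30 eV/Å² vibrates around
3000 cm⁻¹), well depths D_e ∈ [3, 6] eV, equilibrium lengths from a
standard single-bond table with ±3% jitter, angle constants
k_θ ∈ [2, 6] eV/rad² with θ0 ∈ [104°, 120°], and bond-increment charges
(each bond shifts 0.12–0.22 e per Pauling-electronegativity unit toward
its more electronegative partner). Charges therefore sum to zero exactly
and are a function of the bond graph, so symmetry-equivalent atoms carry
identical charges and the dipole surface is learnable from structure.
Reference geometries are minimized with L-BFGS on the analytic gradient to
max |F| < 10⁻³ eV/Å; embeddings whose minimization collapses non-bonded
atoms below 0.5 Å are rejected and retried.

What the oracle does **not** emulate: charge flux (fixed charges cannot
transfer intensity between modes the way real charge redistribution
does), torsional barriers (no dihedral terms — torsions are free),
non-bonded interactions, bond breaking, and any electronic effect.
Passing tests therefore demonstrate workflow correctness on a smooth
anharmonic PES with a benign dipole surface — not chemical accuracy.

## Harmonic analysis and normal-mode sampling

Hessians are central differences of analytic forces (default step
h = 10⁻³ Å), symmetrized as (H + Hᵀ)/2. Frequencies come from the
mass-weighted eigenproblem; eigenvalues below zero are reported as
negative wavenumbers. Modes with |ν̃| < 5 cm⁻¹ are classified rigid
(translations/rotations) — far below any bonded mode of the surrogates.
Mode reduced masses use the 1/Σ|dᵢ|² convention on unit mass-weighted
eigenvectors (an equal-mass diatomic stretch reports m, not m/2).

Initial training geometries trace each non-rigid mode through a
sinusoidal cycle of 30 phases (k = 1…30, so the first frame is already
displaced), with amplitude A set by ½λA² = k_B·300 K — the maximum
harmonic potential energy along the mode equals the thermal quantum. The
first 10 phases per mode are kept, giving 10 × (3N−6) structures per
molecule. Both knobs (phases, reference temperature) are configurable.

The double-harmonic stick spectrum assigns mode m intensity |dμ/dQ_m|²,
with the dipole derivative taken by central differences along the
mass-weighted mode (step 10⁻³ Å·√amu).

## Langevin dynamics

The integrator is the BAOAB splitting with friction in fs⁻¹ (default
0.01 fs⁻¹, 0.5 fs steps). At zero friction it reduces to velocity Verlet,
which the tests exploit as an energy-conservation oracle (drift
< 10⁻⁵ eV over 10⁴ steps). Velocities initialize from the
Maxwell–Boltzmann distribution with centre-of-mass momentum removed.
Trajectories record frames every `record_every` steps, carry velocities
(so runs continue bit-reproducibly from their final frame when the same
RNG stream is passed), and store per-frame dipoles when the calculator
provides them.

Note the friction unit: engines that express the same numeric coefficient
in other time units produce different line widths; 0.01 fs⁻¹ broadens a
vibrational line by roughly 50 cm⁻¹ (FWHM γ/2πc).

**Rigid-rotation projection.** For light molecules the classical free
rotation is fast (a 1 amu diatomic at 300 K rotates at ~170 cm⁻¹) and the
dipole-derivative spectrum develops broad rotational wings that can
dominate or split the vibrational bands. `MDSettings(remove_rotation=True)`
projects the centre-of-mass velocity and rigid rotation (Iω = L, solved
with a pseudo-inverse so linear molecules work) out of the velocities at
every step — the gas-phase vibrational-spectroscopy convention that
isolates internal motion. It is off by default; the analytic-limit
fixtures in the test suite and acceptance script switch it on, together
with a weak bath coupling (friction 0.002 fs⁻¹) so the line width
approaches the resolution limit set by the 1000 fs correlation window.

The production protocol is 5 ps thermalization (discarded) plus 50 ps
production per trajectory, three trajectories with velocity seeds
seed+{0,1,2}, committee-averaged forces, mean spectrum with a sample-std
band.

## The reference potential and its committee

The reference surrogate for the PES is kernel ridge regression of total
energies on a permutation-invariant descriptor: all inverse interatomic
distances, grouped by element-pair class and sorted descending within
each class. Forces are the exact chain-rule gradient of the fit (the sort
permutation is locally constant, so the gradient is valid almost
everywhere). The kernel is a Gaussian plus a weak linear term
(weight 0.01) in centred features — the linear tail keeps extrapolation
smooth instead of flat. Defaults: σ = median pairwise training distance
(recomputed at each refit), ridge 10⁻⁶. The ridge sits deliberately above
the noise floor induced by temporally correlated MD frames; much smaller
values let near-duplicate rows drive the coefficients to noise-amplifying
magnitudes, which visibly corrupts finite-difference Hessians.

**Capacity limit.** The sorted pair-distance descriptor determines a
geometry up to isometry only for ≤ 3 atoms. For larger molecules,
distinct conformations can collide in descriptor space while having
different energies — irreducible label noise that grows as sampling
covers more of configuration space. The bundled active-learning
demonstration therefore uses 2–3-atom surrogates, the regime where the
reference model is a faithful stand-in for a production-grade potential;
the workflow itself is size-agnostic and accepts any model honouring the
`fit`/`predict` contract.

**Committee uncertainty.** A deterministic kernel fit has no
weight-initialization randomness, and a committee of interpolating RBF
fits has a structural pathology: far from the data every member's forces
decay to zero, so the spread *vanishes* exactly where uncertainty should
peak. Members therefore differ by seeded randomized prior functions:
member m (m ≥ 1) adds a random quadratic of the centred features,
½ fᶜᵀQ_m fᶜ with Q_m ~ N(0, 1 eV per squared feature unit), to its
prediction and subtracts it from its fit target. On the training data the
fit absorbs the prior (and its gradient vanishes toward the data
centroid), so members agree in-distribution; away from the data the
quadratic survives, so disagreement grows — the behaviour of seed-varied
neural-network ensembles, realized for a kernel fit. Member 0 carries no
prior and trains on the full split: it is the validation model.

The committee exposes three statistics: component-wise force std across
members; the relative force error √(mean variance)/(RMS force + ε) with
ε = 0.1 eV/Å (small against thermal RMS forces of ~1–2 eV/Å, yet large
enough that the statistic does not explode at turning points where forces
pass through zero), aborting MD above 0.5; and the per-frame acquisition
score, the maximum over atoms of the per-atom force-std norm (reacting to
the worst-described atom; an RMS-over-atoms alternative is available).

**Force source.** Exploration MD during acquisition is driven by the
primary member's forces while the full committee supplies the abort
statistic and the acquisition ranking; production IR runs use
committee-averaged forces. Driving exploration with the committee mean
feeds the prior members' extrapolation tails into the dynamics and
steers trajectories into high-energy plateau regions whose labels degrade
the near-minimum fit — measured directly as a monotonically worsening
harmonic-frequency MAE.

## The dipole model

The reference dipole model regresses per-atom effective charges: each
atom's charge is linear in a local descriptor (element one-hot ⊗
[1, Σ1/r to each element class]), recentred to sum exactly to zero, so
μ̂ = Σ q̂ᵢ(rᵢ − R_COM) is rigorously translation invariant. Against the
oracle's graph-determined charges this is an exact-recovery regime
(held-out MAE well below 20 mDebye on diatomics). Its limits mirror the
oracle's: no charge flux, and symmetry-equivalent atoms necessarily share
a charge.

## Active learning

Iteration 1 trains and evaluates on the initial normal-mode dataset;
from iteration 2 each round (per molecule) continues the stored
exploration trajectory at 300, 500 and 700 K for `explore_ps`, ranks
recorded frames by the acquisition score (ties break toward the earlier
frame), oracle-labels the top 5 per temperature (15 per molecule),
deduplicates by content hash, re-splits the grown dataset 80:20 per
molecule, and retrains all members from scratch with fresh seeds. A run
that trips the sanity abort contributes its pre-abort frames plus the
abort-triggering structure itself (by construction the most uncertain one
seen), and its restart state is re-seeded with fresh velocities from the
last valid frame. The loop stops when the harmonic-frequency MAE of the
first member (absolute values for imaginary entries, rigid modes
excluded, pooled over all molecules' non-rigid modes) drops below
5 cm⁻¹, or after `max_iterations` (default 40).

Committees are per-molecule (the fixed-length per-composition descriptor
cannot span compositions); the harmonic-MAE metric pools all molecules,
so it is comparable to a single multi-molecule model's curve.

Desk-scale demonstration sizes (used by the test suite and
`scripts/acceptance.py`): 8 surrogates of 2–3 atoms, 0.75 ps exploration
segments recorded every 25 steps, 8 iterations, 3 seeds. Under these
conditions the median learning curve ends at less than half its
iteration-1 value (≈ 515 → 227 cm⁻¹). The MAE is not monotone — a
transient rise occurs while newly acquired high-temperature data inflates
the kernel length scale faster than data density grows — matching the
qualitative shape, not the magnitudes, of learning curves obtained with
production-grade potentials.

## IR spectra

The spectrum is the Fourier transform of the autocorrelation of the
dipole time derivative. Numerics: central-difference μ̇ (endpoints
dropped); FFT-based ACF with the biased 1/N normalization (the unbiased
1/(N−k) variant amplifies the tail precisely where the window should
suppress it), truncated at 1000 fs (2000 lags at 0.5 fs); a half-Hann
taper over the ACF support; zero-padding to the next power of two ≥ 16×
the depth (sub-2 cm⁻¹ grid — cosmetic interpolation only, adding no
information); magnitude of the real FFT. The ACF is not normalized at lag
zero, preserving relative band intensities across a spectrum. No quantum
correction factor is applied to the classical ACF. Intensities are in
arbitrary units; absolute cross-sections are out of scope.

## Spectral comparison

Spectra are mapped onto the reference grid by linear interpolation
(points outside the source support become zero, with a warning).
Experimental-style baselines are removed by asymmetric least squares
(smoothness λ = 10⁵, asymmetry p = 0.01, 10 reweighting iterations —
the knobs are configurable and the defaults are a documented stand-in
choice); negative residuals clip at zero. PCC is computed on raw
regridded intensities (it is scale invariant); the Wasserstein distance
treats both spectra as unit-mass distributions over wavenumber, so it
reads in cm⁻¹ and is invariant to intensity scaling. By default only the
input designated experimental is baseline-corrected.

## Test-set construction

Per molecule: a 300 K MD trajectory (protocol scale 100 ps with 2000
uniformly spaced frames; desk scale shrinks both proportionally, e.g.
2–10 ps with 120–200 frames, without changing selection counts), a 2-body
descriptor (Gaussian-broadened histograms of inverse pairwise distances,
one channel per element pair, 24 bins over 0.1–2.0 Å⁻¹, width 0.05 Å⁻¹),
k-means with k = 5 (k-means++ init, fixed seed, unstandardized features —
all channels share units), and 4 structures drawn uniformly without
replacement per cluster: 20 per molecule, 480 at the 24-molecule protocol
scale. The transferability variant keeps k = 5 with 10 per cluster
(50 per molecule, 400 at the 8-molecule scale). Three-body descriptor
terms are omitted — two-body channels separate the surrogate
conformations — and flagged extensible. Frame indices and cluster labels
are recorded as provenance.

## Known limitations

- Fixed point charges: no charge flux, so intensity redistribution
  between modes is absent by construction.
- The pair descriptor's ≤ 3-atom injectivity bound (above); larger
  molecules need richer descriptors or an external potential plugged into
  the same interface.
- The committee's absolute uncertainty scale is set by the prior scale
  (1 eV/feature²) and is meaningful as a *ranking*, not as a calibrated
  error bar.
- Classical nuclei throughout: no zero-point motion, tunnelling,
  combination bands or Fermi resonances.
- Only Langevin dynamics is implemented; reference trajectories use the
  same thermostat as production runs (thermostat identity is immaterial
  to the properties tested here).
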