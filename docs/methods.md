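# Methods

## Free energy model

The free energy change of an alchemical transformation is estimated by
thermodynamic integration,

ΔG = ∫₀¹ ⟨∂V/∂λ⟩ dλ ≈ Σᵢ wᵢ ⟨∂V/∂λ⟩ᵢ,

with λ nodes and weights from an n-point Gauss–Legendre rule mapped
affinely from [−1, 1] to (0, 1) (weights halved so they sum to 1). Nodes
and weights come from `numpy.polynomial.legendre.leggauss`, which matches
published tables to well beyond 5 decimals for n ≤ 16. The n = 12 rule is
the production default: its extreme nodes (0.00922, 0.99078) avoid the
endpoint singularities that softcore potentials are designed to tame, so no
endpoint extrapolation is performed. Gauss–Legendre is exact for polynomial
integrands up to degree 2n−1; for the smooth ⟨∂V/∂λ⟩ profiles of
single-residue transformations the quadrature error is far below the
statistical error.

A relative binding free energy closes a thermodynamic cycle:
ΔΔG_b = ΔG(mutation in complex) − ΔG(mutation in apo protein), with
σ²(ΔΔG) = σ²(complex) + σ²(apo) because the two legs are independent
simulations. Mutations that change the protein's formal charge carry a
co-ion plan: annealing a negative side chain or creating a positive one
(Δq = +1) converts a Na⁺ ion into water, annealing a positive side chain
(Δq = −1) does the reverse, keeping the box neutral. Formal charges use the
pH-7 convention (Asp/Glu −1, Lys/Arg +1, His neutral); |Δq| > 1 cannot
arise from a single mutation at fixed protonation and is rejected. The
plan is bookkeeping validated as a rule — this package runs no solvated
simulation, so the co-ion's position in the box is out of scope.

## Uncertainty of autocorrelated series

Each window's ∂V/∂λ series is processed as:

1. discard the first ⌊f·N⌋ samples (default f = 0.1), per window
   independently;
2. estimate the statistical inefficiency g = 1 + 2 Σₜ C(t), where C(t) is
   the normalized autocovariance (biased FFT estimator) summed until its
   first crossing below zero, clamped to g ≥ 1. The initial-negative
   truncation is simple and robust at the series lengths used here
   (10³–10⁶ samples); on AR(1) data it recovers the analytic
   g = (1+φ)/(1−φ) within 10 % at N = 10⁶ for φ up to 0.9;
3. subsample every ⌈g⌉-th retained frame starting at the first;
4. report the mean over **all** retained samples and the SEM from the
   subsample's variance (n−1 denominator) divided by the subsample size.

Computing the variance on the subsample rather than inflating the
full-sample variance by g is a convention choice; the two agree
asymptotically. A constant window (e.g. a null transformation with
∂V/∂λ ≡ 0) is assigned g = 1 and SEM = 0 rather than an error, since its
mean is exact; the standalone inefficiency estimator still rejects
zero-variance input, where g is undefined.

Convergence is monitored by recomputing ΔΔG on cumulative prefixes
(forward) and suffixes (reverse) of every window after the discard; on
stationary data the two profiles end on the identical full-data value and
their interior gap stays within combined statistical noise.

## Atom mapping

Residue topologies for the 20 standard amino acids are stored with
AMBER-style atom naming (HB2/HB3 β-hydrogens, ε-protonated neutral
histidine, proline without an amide H, glycine with HA2/HA3). The
`default` scheme pairs only the backbone (N, H, CA, HA, C, O, with
HA2↔HA across a glycine mutation) and softcores every side-chain atom.
The `mcs` scheme grows a maximal common connected substructure outward
from the paired backbone: a candidate pair is accepted when elements match
and every already-paired neighbour maps to a bonded neighbour on the other
side, so the paired subgraphs stay bond-isomorphic by construction. Ties
are broken deterministically (heavy atoms before hydrogens, then
lexicographic name), which resolves symmetric ring branches (CD1/CD2)
consistently and pairs surplus hydrogens on a shared heavy atom in name
order — leaving exactly one Ser β-hydrogen unique in THR→SER. A validator
rechecks partition exactness, element matches, bond preservation and core
connectivity for any mapping, including hand-written ones. The `mcs`
scheme is advisory: chemically dubious pairings (e.g. mapping a charged
carboxylate onto an alanine methyl) remain the `default` scheme's domain.

## Conformational states

States of a scalar descriptor (a distance in Å, or a dihedral in degrees
with 360° period) are maximal contiguous runs of occupied histogram bins
separated by empty bins, wrapped across the periodic boundary. Defaults:
72 bins (5°) for dihedrals, 0.2 Å bin width for distances — resolutions at
which well-separated side-chain basins (≳1 Å or ≳30° apart, widths a few
bins) split cleanly. States below 1 % occupancy merge into the state with
the nearest mode to suppress noise blips. The representative frame of a
state is the one whose value is closest (circularly, if periodic) to the
state's mode, earliest frame on ties; exact occupancy ties resolve to the
lower-mode state.

## Kd benchmark

ΔG_b = RT·ln K_d with R = 1.9872×10⁻³ kcal/(mol·K), so
ΔΔG_b = RT·ln(K_d,mut/K_d,wt). The conversion temperature defaults to
298.15 K, which reproduces the published experimental column to its
printed 2 decimals (the simulation temperature, 303 K, does not; both are
exposed). Experimental uncertainties follow first-order propagation using
the variant's K_d only, σ = RT·σ_Kd/K_d — a convention inferred by
reproducing the printed uncertainty column (it reproduces every entry
except one, V36A, whose printed 0.03 appears truncated from 0.035).
Lower-bound constants ("> x") are converted at x, flagged, and enter the
statistics as point values. The packaged table keeps the published
experimental values alongside the K_d columns because one row (L174A,
printed 0.54 vs K_d-derived 1.50 kcal/mol) is internally inconsistent;
statistics use the published column by default, with a flag to switch to
the K_d-derived one. The wild-type self-transformation (a control, not a
mutation) is excluded from MAE/r by default and includable by flag.
Summary lines round MAE to 1 decimal and r to 2, mirroring the published
precision; full-precision values are always carried.

## Synthetic data

The generators define the validation conditions and return their ground
truth alongside the data:

* **Profile windows** — m(λ) polynomial mean (truth ∫₀¹ m dλ = Σcₖ/(k+1))
  plus stationary AR(1) noise (default σ = 1 kcal/mol, φ = 0.9, i.e.
  g ≈ 19 — a deliberately hard autocorrelation stress test) and an
  optional exponential transient that decays to < 1 % of its amplitude
  within the first 10 % of each window, matching the discard fraction so
  the discard step is exercised meaningfully. Default 5000 samples per
  window.
* **Harmonic toy system** — Metropolis sampling of x under
  V = ½[(1−λ)k₀+λk₁]x², recording ∂V/∂λ = ½(k₁−k₀)x²; exact
  ΔG = (kT/2)·ln(k₁/k₀). Step size is auto-tuned toward ~40 % acceptance
  over 25 discarded burn-in rounds of 200 steps.
* **Softcore LJ pair** — one pair in a sphere of radius L/2 with the
  separation-shifted softcore form
  V(r;λ) = 4ελ[(α(1−λ)+(r/σ)⁶)⁻² − (α(1−λ)+(r/σ)⁶)⁻¹], α = 0.5.
  This standard one-parameter form is chosen for the package on its own
  merits; only self-consistency against the independent reference
  ΔG = −kT·ln(Z₁/Z₀), with Z(λ) = ∫ r² e^{−V/kT} dr evaluated by adaptive
  quadrature, is claimed — not equality with any particular MD engine's
  softcore. The radial Metropolis move carries the r² volume Jacobian in
  its acceptance ratio. λ = 1 recovers plain LJ; λ = 0 is non-interacting.
* **Two-state series** — hidden Markov chain with transition matrix
  P = (1−ρ)I + ρ·1wᵀ (stationary occupancies exactly w; default switching
  rate ρ = 0.1, i.e. mean dwell 10 frames, typical of a side-chain
  descriptor sampled every ~100 ps) and Gaussian emissions per state.

All randomness flows from one explicit seed through
`numpy.random.SeedSequence` spawning; equal seeds give bit-identical
output. The Metropolis kernels consume pre-drawn random arrays, so the
optional numba JIT changes speed only.

What the synthetic data does **not** emulate: real MD noise is neither
Gaussian nor exactly AR(1) (it has fat tails and multiple correlation
times), slow conformational transitions can make the discard-fraction
convention inadequate, and the toy systems have one degree of freedom.
Passing tests therefore demonstrate the correctness of the estimators and
bookkeeping under known conditions, not the adequacy of any sampling
protocol for real proteins. The published per-mutation computed ΔΔG_b
values require microsecond-scale explicit-solvent MD and are carried only
as benchmark fixture data.

## Problem sizes and numerical choices

The validation suites use 20 replicates × 12 windows × 20 000 MC steps for
the harmonic recovery check, 50 000 steps per window for the softcore
check, N = 10⁶ for the AR(1) inefficiency calibration and N = 10⁴ for
occupancy recovery — sizes at which the 3-SEM acceptance bands are tight
enough to catch estimator bias while each suite completes in seconds.
Schedule weights must sum to 1 within 10⁻⁴ on read; window λ values must
match their schedule node within 10⁻⁶; floats round-trip through all text
formats at full precision (`%.17g` / JSON repr). Known limitations: the
initial-negative ACF truncation overestimates g slightly on short, nearly
white series (visible as mild SEM inflation below ~10⁴ samples), and the
greedy MCS growth is maximal only per growth front — for the
backbone-anchored residue graphs in scope it attains the true maximum
common substructure, verified by the mirror-symmetry and validator
property tests.
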