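# Methods

This note records the model, algorithms, parameter choices and known
numerical limitations of the `tjumpxtal` package.

## Physical model

The package analyses pump-probe serial crystallography data in which a
mid-IR pulse heats the solvent and a small fraction *f* of protein
molecules responds by shifting to an excited conformation. The crystal-
averaged electron density is then (1−f)·ρ_ground + f·ρ_excited, and the
observable consequences are (i) small changes in merged structure-factor
amplitudes, (ii) paired positive/negative features in isomorphous
difference maps, and (iii) a shift in the solution-scatter background of
pumped shots.

### Temperature-jump estimate (`thermo`)

The jump is estimated by a linear Beer–Lambert chain for a pure-water
cylinder illuminated by one pulse:

    eps   = A_1443 / (l_ref · M)      = 12.83 / 55.56 = 0.2309 cm⁻¹M⁻¹
    A     = eps · l · M               = 0.09622  (l = 7.5e-3 cm)
    q     = I · A                     = 5.20e-5 J  (I = 5.4e-4 J)
    V     = r²·π·l, m = V·ρ           = 5.89e-7 g  (r = 5.0e-3 cm)
    ΔT    = q / (m·c)                 = 21.1 K  (c = 4.184 J/g/K)

Two deliberate conventions:

- The absorbed fraction is taken to be the base-10 absorbance A itself.
  The physically exact decadic fraction 1 − 10⁻ᴬ is ≈ 2.07× larger at
  A ≈ 0.096 (ln 10 to first order) and is available via
  `tjump_estimate(exact_absorption=True)`, which yields ≈ 43.5 K. The
  default reproduces the linear chain above.
- The attenuation depth is reported as 1/A_1443 ≈ 779 µm.

Heat diffusion, viscogen/crystal heat-capacity corrections and radial
gradients are out of scope; the estimate is an upper bound.

### Shot classification (`scatter_svd`)

1. **Azimuthal averaging.** Detector pixels are binned by their
   calibrated q; per-bin means are then smoothed with a sliding median
   (window 15 bins, shrinking symmetrically at the edges) to suppress
   Bragg spikes, which are orders of magnitude above the diffuse
   background but occupy few pixels per bin.
2. **Scaling.** Each curve is scaled onto the ensemble mean by a
   closed-form least-squares factor computed over 2.0–2.5 Å⁻¹, a region
   dominated by the water peak flank. Curves whose factor deviates from
   the ensemble median by more than 5× the median absolute deviation
   (jet clogs, blank shots) are culled.
3. **SVD.** The scaled curves over 1.0–2.7 Å⁻¹ form the matrix rows;
   `numpy.linalg.svd` factorizes it, with a sign convention making each
   right-singular vector's largest-magnitude entry positive.
4. **Classification.** The u₁ loadings are split by sign, the decision
   threshold refined to the midpoint of the two class means, and the
   class agreeing better with the laser-diode record is called "light".
   If the two classes are separated by less than 3× the pooled
   within-class standard deviation the split is flagged degenerate (a
   single normal distribution split at its mean separates by 2.65×, so
   only clearly larger ratios indicate genuine bimodality).

### Difference maps (`realspace`)

Difference amplitudes ΔF = |F_t| − |F_dark| are formed on the common
Miller indices, with σ(ΔF) combined in quadrature and phases taken from
the dark model by default (a phased set or raw array can be supplied
instead — the phase source matters and is an explicit argument).
Per-reflection weights follow

    w = [ 1 + σ²(ΔF)/⟨σ²(ΔF)⟩ + 0.05·|ΔF|²/⟨|ΔF|²⟩ ]⁻¹

with global means (an equal-count resolution-shell variant is available
behind `by_shell`). When every σ is zero — exactly noise-free synthetic
data — the σ term is dropped rather than producing 0/0.

Maps are synthesized from coefficients w·ΔF·exp(iφ) on a grid with
spacing ≤ 0.25 × d_min per axis (FFT-friendly dimensions). The
crystallographic convention ρ(x) = (1/V)·Σ F(h)·e^(−2πih·x) is realized
by placing F(h) at index −h for numpy's inverse FFT (positive-exponent)
and the Friedel mate conj(F) at +h; F(000) is omitted so maps have zero
mean, and values are in e⁻/Å³.

**IADDAT** integrates |ρ| ≥ 0.04 e⁻/Å³ voxels lying within 2.5 Å
(minimum-image, P1) of any non-water atom of a residue, dividing each
residue's sum by its atom count. A voxel may count toward several
residues. **RSCC** zeroes sub-threshold voxels (same 0.04 default)
independently in each map and computes the Pearson correlation over all
voxels, returning None when a thresholded map has zero variance.
**Simulated B-inflation maps** are synthesized from the complex
difference F(1.2·B) − F(B), validated against the closed-form Gaussian
difference density.

### Extrapolated structure factors (`esfm`)

    |F_ESF| = N · w · ΔF + |F_dark|,   N = 1/f

with σ propagated as √((N·w·σ(ΔF))² + σ_dark²). Negative raw amplitudes
are clamped to zero and counted (or dropped under `clamp_policy="drop"`);
the clamp count is an over-extrapolation diagnostic. Occupancy recovery
fits, for each N, a single occupancy o ∈ [0, 1] minimizing
Σ(|F_ESF| − |(1−o)·F_ground + o·F_excited|)² by bounded scalar search
(xatol 1e-4).

### Anisotropic network model (`anm`)

One node per residue at the C-alpha; springs of constant γ (default 1.0)
connect nodes within 15 Å. Off-diagonal Hessian blocks are
−γ·ddᵀ/|d|²; diagonals are the negative row sums. A disconnected
contact network (or > 6 numerically null modes) raises. The minimum node
count is 2 (5 rigid-body modes, one stretch mode at exactly 2γ — the
textbook check). `combine_modes` forms V_total = Σ √(1/λᵢ)·Vᵢ over the
n softest nonzero modes, and `project_coords` moves every atom of a
residue by its node vector times a caller-chosen amplitude.

## Synthetic generator

`SyntheticSpec` defaults describe a deliberately small but non-trivial
problem: 8 four-atom (N/CA/C/O) residues along a helical path in a
16 × 18 × 14 Å P1 cell, d_min 1.6 Å (≈ 2,000 reflections), excited
fraction 0.10, the middle two residues displaced rigidly by 0.5 Å, and
2% relative Gaussian noise on amplitudes (σ columns record the true
noise level). Mixing is done in complex structure-factor space,
|{(1−f)·F_g + f·F_e}|, not on amplitudes. Structure factors come from
direct summation with bundled 4-Gaussian + constant form factors
(H, C, N, O, P, S) and isotropic Debye–Waller damping; the
implementation is validated against an independent real-space/FFT
route. Scatter shots are a water-like background plus a localized
antisymmetric difference shape on light shots, interleaved
light/dark1/dark2 with per-shot scale jitter and additive noise;
detector images are rendered by an affine q(r) calibration with
optional 100× spike pixels.

What the generator does **not** emulate: space-group symmetry (all P1),
anomalous scattering, partiality/merging statistics, solvent
contribution, non-isomorphism, and phase error in the dark model.

## Known limitation: occupancy recovery under extrapolation

On noise-free data with f = 0.10 the recovered occupancy at N = 10
reaches ≈ 0.69, not 1.0, and the corresponding acceptance test is left
failing deliberately. Two systematic effects cap it:

1. **Scalar amplitude approximation.** |(1−o)·F_g + o·F_e| is a convex
   function of o for each reflection, and the ESFM relation is its
   tangent at o = 0 scaled by N. Tangent extrapolation of a convex
   function underestimates the value at o = 1, so the extrapolated
   amplitudes systematically undershoot |F_excited|. Even with w ≡ 1
   the fitted occupancy at N = 10 is ≈ 0.82.
2. **Weighting bias.** The |ΔF|² term of the weight suppresses exactly
   the largest, most signal-carrying differences (signal-weighted mean
   weight ≈ 0.8 at zero noise), further shrinking the extrapolated
   excited-state contribution.

Both effects were verified by (a) showing the occupancy fit itself is
unbiased when fed exact |(1−o)·F_g + o·F_e| amplitudes (it recovers o
to 2e-4), and (b) sweeping the displacement toward zero, where the
ceiling rises only to ≈ 0.79. The gap is therefore a property of the
method being modelled, not an implementation error, and the acceptance
assertion was not tuned to pass.

## Problem sizes and runtimes

The full test suite (164 tests) runs in ≈ 3 s on one CPU. The largest
cases are the 3 × 3,000-shot classification sweep (< 1 s), the
2,057-reflection map/ESFM pipelines (< 1 s each), and the 64³-grid FFT
oracle for the structure-factor cross-check (< 1 s).
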