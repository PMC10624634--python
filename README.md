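# tjumpxtal

Analysis toolkit for temperature-jump (T-jump) time-resolved serial
femtosecond crystallography. A nanosecond mid-IR laser pulse (1,443 nm,
exciting the water O–H stretch combination band) heats the liquid jet
carrying protein microcrystals; interleaved pump-on/pump-off XFEL
diffraction snapshots then track how the protein's conformational
ensemble relaxes on nanosecond-to-microsecond timescales. This package
implements the post-merging analysis stages of such an experiment and a
synthetic two-state data generator for validating every stage against
known ground truth.

## What it does

- **Thermodynamics** (`thermo`): Beer–Lambert estimate of the solvent
  temperature jump from the pulse energy, jet thickness and water
  absorbance, with every intermediate exposed.
- **Shot classification** (`scatter_svd`): azimuthal averaging of
  detector images with median-filter despiking, least-squares scaling of
  solution-scatter curves, singular value decomposition, and u₁-based
  pump-on/pump-off classification cross-checked against the laser diode.
- **Difference maps** (`realspace`): weighted isomorphous difference
  structure factors (per-reflection weights down-weighting uncertain and
  outlier differences), Fourier synthesis at 0.25 × d_min sampling,
  per-residue integrated absolute difference density above threshold
  (IADDAT), thresholded real-space correlation (RSCC), and simulated
  B-inflation difference maps for separating global thermal motion from
  conformational change.
- **Extrapolated structure factors** (`esfm`): |F_ESF| = N·w·ΔF +
  |F_dark| amplification of a small excited-state population, and an
  occupancy-recovery fit that measures how much of a candidate excited
  conformation the extrapolated amplitudes support.
- **Elastic network modes** (`anm`): anisotropic network model on
  C-alpha nodes, mode combination weighted by √(1/λ), and projection of
  the combined mode onto atomic coordinates.
- **Synthetic data** (`synthetic_data`): a toy two-state crystal
  (helical chain of small residues, loop displacement, B-factor
  inflation, calibrated Gaussian noise) with structure factors from
  direct summation over bundled atomic form factors, plus synthetic
  solution-scatter shot series and detector images.

All file I/O uses standard formats (PDB, MTZ, CCP4/MRC maps via gemmi;
CSV/TSV for tables).

## Worked example

The temperature-jump estimate for the reference conditions (540 µJ
pulse, 75 µm jet, pure water):

```sh
$ tjump-xtal thermo
epsilon            = 0.2309 cm^-1 M^-1
A(path)            = 0.09622
q absorbed         = 5.2e-05 J
illuminated volume = 5.89e-07 cm^3
heated mass        = 5.89e-07 g
delta T            = 21.1 K
attenuation depth  = 779 um
```

A full synthetic round trip — simulate a crystal in which 10% of
molecules shift a two-residue loop by 0.5 Å, build the weighted
difference map, and locate the signal per residue:

```python
from tjumpxtal.synthetic_data import SyntheticSpec, simulate_tjump_dataset
from tjumpxtal.realspace import (difference_structure_factors, weights,
                                 synthesize_map, iaddat)
from tjumpxtal.esfm import make_esfm_series, occupancy_recovery

spec = SyntheticSpec(seed=11)          # f = 0.10, 0.5 A loop shift, 2% noise
data = simulate_tjump_dataset(spec)    # 2,057 reflections to 1.6 A

ds = weights(difference_structure_factors(data.f_t, data.f_dark1))
grid = synthesize_map(ds)              # 40 x 45 x 35 grid, 0.4 A spacing
profile = iaddat(grid, data.ground)
print(dict(zip(profile.residue_ids, profile.values.round(3))))
# {('A', 1): 0.0, ('A', 2): 0.0, ('A', 3): 0.021, ('A', 4): 0.14,
#  ('A', 5): 0.107, ('A', 6): 0.0, ('A', 7): 0.0, ('A', 8): 0.0}
```

The IADDAT profile localizes the difference density to the displaced
loop (residues 4–5) and is flat elsewhere. Occupancy recovery from the
extrapolated amplitudes rises monotonically with the extrapolation
factor N:

```python
series = make_esfm_series(ds, data.f_dark1, n_max=12)
curve = occupancy_recovery(data.ground, data.excited, series,
                           true_fraction=spec.excited_fraction)
print(curve.occupancies.round(2))
# [0.06 0.12 0.18 0.23 0.29 0.34 0.39 0.44 0.49 0.53 0.57 0.61]
```

The same pipeline is available from the command line: `tjump-xtal
simulate`, `diffmap`, `iaddat`, `rscc`, `esfm`, `anm`, `scatter-svd`
and `thermo` (see `--help` on each; all flags can also come from a
YAML/TOML file via `--config`).

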