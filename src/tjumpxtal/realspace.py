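"""Weighted difference density, IADDAT, map correlations.

Light-minus-dark amplitude differences are noisy, and reflections with
large uncertainty or outlier magnitude would dominate an unweighted
Fourier difference synthesis. Each difference amplitude is therefore
down-weighted by

    w_hkl = [ 1 + sigma^2(dF)/<sigma^2(dF)> + alpha |dF|^2/<|dF|^2> ]^-1

with alpha = 0.05 and <.> arithmetic means over the joined reflection
set. Difference maps are synthesized with coefficients w * dF *
exp(i phi_dark) on a grid sampled at 0.25 x d_min and carry absolute
electron-density units (1/V_cell scaling, F000 omitted), so the
0.04 e-/A^3 integration threshold is meaningful.

IADDAT (integrated absolute difference density above threshold) sums
|rho| over voxels that exceed the threshold and lie within a cutoff
radius of a residue's non-water atoms, averaged per residue. RSCC is a
Pearson correlation between two maps after zeroing sub-threshold voxels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import gemmi
import numpy as np
import pandas as pd
from scipy.fft import ifftn, next_fast_len

from tjumpxtal.core_model import CrystalModel, ReflectionSet, UnitCell
from tjumpxtal.synthetic_data import generate_hkl, structure_factors_complex

logger = logging.getLogger(__name__)

WEIGHT_ALPHA = 0.05
GRID_RESOLUTION_FACTOR = 0.25


# ---------------------------------------------------------------------------
# difference structure factors and weights
# ---------------------------------------------------------------------------

@dataclass
class DifferenceSet:
    """Per-reflection amplitude differences with uncertainties and weights.

    Defined only on Miller indices present in both input sets. ``phase``
    holds the model phases (degrees) used for map synthesis; ``weight``
    is None until :func:`weights` fills it.
    """

    hkl: np.ndarray
    delta_f: np.ndarray
    sig_delta_f: np.ndarray
    phase: np.ndarray
    cell: UnitCell
    d_min: float
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        for name in ("delta_f", "sig_delta_f", "phase"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)
            if np.any((self.weight <= 0) | (self.weight > 1.0 + 1e-12)):
                raise ValueError("weights must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.hkl)


def difference_structure_factors(
    f_t: ReflectionSet,
    f_dark: ReflectionSet,
    phases: ReflectionSet | np.ndarray | None = None,
) -> DifferenceSet:
    """Inner-join two amplitude sets into dF = |F_t| - |F_dark|.

    Sigmas combine in quadrature. Phases default to those carried by
    ``f_dark`` (the dark-model phases); pass a phased
    :class:`ReflectionSet` (e.g. calculated from a model refined against
    F_t) or a raw degree array to switch the phase source.
    """
    if not f_t.cell.isclose(f_dark.cell, rel_tol=5e-3):
        raise ValueError("unit cells differ by more than 0.5%")
    index_t = {tuple(h): i for i, h in enumerate(f_t.hkl)}
    phase_set = f_dark if phases is None else phases
    rows: list[tuple[int, int]] = []
    for j, h in enumerate(f_dark.hkl):
        i = index_t.get(tuple(h))
        if i is not None:
            rows.append((i, j))
    if not rows:
        raise ValueError("no Miller indices in common between the two sets")
    it, jd = np.array(rows).T
    if isinstance(phase_set, ReflectionSet):
        if phase_set.phase is None:
            raise ValueError("phase source carries no phases")
        pidx = {tuple(h): i for i, h in enumerate(phase_set.hkl)}
        missing = [tuple(h) for h in f_dark.hkl[jd] if tuple(h) not in pidx]
        if missing:
            raise ValueError(f"{len(missing)} reflections lack phases")
        phase = np.array([phase_set.phase[pidx[tuple(h)]] for h in f_dark.hkl[jd]])
    else:
        phase = np.asarray(phase_set, dtype=float)[jd]
    return DifferenceSet(
        hkl=f_dark.hkl[jd],
        delta_f=f_t.f[it] - f_dark.f[jd],
        sig_delta_f=np.sqrt(f_t.sigf[it] ** 2 + f_dark.sigf[jd] ** 2),
        phase=phase,
        cell=f_dark.cell,
        d_min=max(f_t.d_min, f_dark.d_min),
    )


def weights(ds: DifferenceSet, alpha: float = WEIGHT_ALPHA,
            by_shell: bool = False, n_shells: int = 10) -> DifferenceSet:
    """Fill per-reflection weights into a copy of the difference set.

    The normalizing means are global over the whole set by default; with
    ``by_shell`` they are taken within equal-count resolution shells
    instead (an alternative some weighting schemes use).
    """
    if len(ds) == 0:
        raise ValueError("empty difference set")
    sig2 = ds.sig_delta_f ** 2
    df2 = ds.delta_f ** 2
    if by_shell and len(ds) >= n_shells:
        d = ds.cell.d_spacing(ds.hkl)
        order = np.argsort(-d)  # low resolution first
        shell = np.empty(len(ds), dtype=int)
        shell[order] = np.minimum(np.arange(len(ds)) * n_shells // len(ds), n_shells - 1)
        mean_sig2 = np.array([sig2[shell == s].mean() for s in range(n_shells)])[shell]
        mean_df2 = np.array([df2[shell == s].mean() for s in range(n_shells)])[shell]
    else:
        mean_sig2 = np.full(len(ds), sig2.mean())
        mean_df2 = np.full(len(ds), df2.mean())
    if np.all(sig2 == 0):
        logger.info("all sigma(dF) are zero; dropping the sigma term of the weight")
        sig_term = np.zeros(len(ds))
    else:
        sig_term = sig2 / mean_sig2
    df_term = np.where(mean_df2 > 0, alpha * df2 / np.where(mean_df2 > 0, mean_df2, 1.0), 0.0)
    w = 1.0 / (1.0 + sig_term + df_term)
    return replace(ds, weight=w)


# ---------------------------------------------------------------------------
# map synthesis
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Real-space density samples over one unit cell, in e-/A^3."""

    values: np.ndarray
    cell: UnitCell
    d_min: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("density grid must be 3D with >= 2 samples per axis")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite density values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_frac_coords(self) -> np.ndarray:
        """Fractional coordinates of every voxel centre, shape (n_voxels, 3)."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx) / nx, np.arange(ny) / ny,
                                 np.arange(nz) / nz, indexing="ij")
        return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)

    def write_ccp4(self, path: str) -> None:
        """Write as a CCP4/MRC mode-2 map with cell metadata in the header."""
        grid = gemmi.FloatGrid(*self.shape)
        grid.set_unit_cell(self.cell.to_gemmi())
        grid.spacegroup = gemmi.SpaceGroup("P1")
        np.asarray(grid, dtype=np.float32)[...] = self.values.astype(np.float32)
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header(2, True)
        ccp4.write_ccp4_map(path)

    @classmethod
    def read_ccp4(cls, path: str) -> "DensityGrid":
        ccp4 = gemmi.read_ccp4_map(path)
        values = np.array(ccp4.grid, copy=True)
        return cls(values=values, cell=UnitCell.from_gemmi(ccp4.grid.unit_cell))


def map_grid_shape(cell: UnitCell, d_min: float,
                   factor: float = GRID_RESOLUTION_FACTOR) -> tuple[int, int, int]:
    """Grid dimensions so the spacing is <= factor * d_min along each axis."""
    spacing = factor * d_min
    dims = []
    for length in (cell.a, cell.b, cell.c):
        dims.append(next_fast_len(max(2, math.ceil(length / spacing))))
    return tuple(dims)


def synthesize_from_complex(hkl: np.ndarray, coeffs: np.ndarray, cell: UnitCell,
                            d_min: float) -> DensityGrid:
    """Fourier synthesis from half-sphere complex coefficients.

    Friedel mates are completed as conjugates, the result is scaled by
    1/V_cell, and F(000) is omitted, so the grid has zero mean and
    absolute density units.
    """
    shape = map_grid_shape(cell, d_min)
    hkl = np.asarray(hkl, dtype=int)
    hmax = np.abs(hkl).max(axis=0)
    if np.any(2 * hmax + 1 > np.array(shape)):
        # guard against index aliasing on unusually coarse grids
        shape = tuple(next_fast_len(int(2 * m + 2)) for m in hmax)
    # crystallographic convention rho(x) = (1/V) sum F(h) exp(-2 pi i h.x):
    # F(h) sits at index -h so numpy's ifftn (positive exponent) applies it
    arr = np.zeros(shape, dtype=complex)
    neg = tuple(((-hkl) % np.array(shape)).T)
    arr[neg] = coeffs
    idx = tuple((hkl % np.array(shape)).T)
    arr[idx] = np.conj(coeffs)
    n_total = np.prod(shape)
    rho = np.real(ifftn(arr)) * n_total / cell.volume
    return DensityGrid(values=rho, cell=cell, d_min=d_min)


def synthesize_map(ds: DifferenceSet, use_weights: bool = True) -> DensityGrid:
    """Weighted difference Fourier synthesis at 0.25 x d_min sampling."""
    if use_weights and ds.weight is None:
        raise ValueError("difference set has no weights; run weights() first")
    if ds.phase is None or not np.isfinite(ds.phase).all():
        n_bad = int(np.sum(~np.isfinite(ds.phase))) if ds.phase is not None else len(ds)
        raise ValueError(f"{n_bad} reflections lack phases")
    amp = ds.delta_f * (ds.weight if use_weights else 1.0)
    coeffs = amp * np.exp(1j * np.radians(ds.phase))
    return synthesize_from_complex(ds.hkl, coeffs, ds.cell, ds.d_min)


def bscaled_difference(model: CrystalModel, scale: float = 1.2,
                       d_min: float = 1.6) -> DensityGrid:
    """Simulated difference map for a uniform B-factor inflation.

    Structure factors are calculated from the model as-is and from a copy
    with every isotropic B multiplied by ``scale``; the map is synthesized
    from the complex difference F_scaled - F_original. A uniform B
    increase produces negative density at atomic centres surrounded by
    positive halos — the signature of increased thermal motion.
    """
    if scale <= 0:
        raise ValueError("B scale must be positive")
    hkl = generate_hkl(model.cell, d_min)
    f0 = structure_factors_complex(model, hkl)
    f1 = structure_factors_complex(model.with_bscale(scale), hkl)
    return synthesize_from_complex(hkl, f1 - f0, model.cell, d_min)


# ---------------------------------------------------------------------------
# IADDAT
# ---------------------------------------------------------------------------

@dataclass
class IADDATConfig:
    """Integration settings: density threshold in e-/A^3, radius in A."""

    threshold: float = 0.04
    radius: float = 2.5
    exclude_water: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.radius <= 0:
            raise ValueError("threshold and radius must be positive")


@dataclass
class IADDATProfile:
    """Per-residue average integrated absolute difference density."""

    residue_ids: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("IADDAT values must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        """Values scaled by the profile maximum (for display), zeros if flat."""
        m = self.values.max() if len(self.values) else 0.0
        return self.values / m if m > 0 else np.zeros_like(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [c for c, _ in self.residue_ids],
            "resnum": [r for _, r in self.residue_ids],
            "iaddat": self.values,
            "iaddat_normalized": self.normalized,
        })


def iaddat(grid: DensityGrid, model: CrystalModel,
           cfg: IADDATConfig | None = None) -> IADDATProfile:
    """Integrate |rho| above threshold around each residue.

    A voxel contributes to a residue when |rho| >= threshold and the
    voxel centre lies within the cutoff radius (minimum-image convention
    in P1) of any of that residue's non-water atoms; a voxel may count
    toward several residues. Each residue's sum is divided by its atom
    count.
    """
    cfg = cfg or IADDATConfig()
    if not grid.cell.isclose(model.cell, rel_tol=5e-3):
        raise ValueError("grid and model cells disagree")
    work = model.select(waters=False) if cfg.exclude_water else model
    if len(work) == 0:
        raise ValueError("model has no non-water atoms")

    res_ids = work.residue_ids
    flat = np.abs(grid.values).ravel()
    supra = np.where(flat >= cfg.threshold)[0]
    values = np.zeros(len(res_ids))
    if supra.size:
        vox_frac = grid.voxel_frac_coords()[supra]
        vox_rho = flat[supra]
        orth = model.cell.orthogonalization_matrix()
        res_index = {rid: i for i, rid in enumerate(res_ids)}
        atom_counts = np.zeros(len(res_ids))
        # voxel -> residue membership via min-image distance to each atom
        hit = np.zeros((len(res_ids), supra.size), dtype=bool)
        for at in work.atoms:
            i = res_index[(at.chain, at.resnum)]
            atom_counts[i] += 1
            delta = vox_frac - at.frac
            delta -= np.round(delta)
            dist = np.linalg.norm(delta @ orth.T, axis=1)
            hit[i] |= dist <= cfg.radius
        for i in range(len(res_ids)):
            values[i] = vox_rho[hit[i]].sum() / atom_counts[i]
    return IADDATProfile(residue_ids=res_ids, values=values)


def delta_iaddat(p1: IADDATProfile, p2: IADDATProfile) -> IADDATProfile:
    """Per-residue |IADDAT_1 - IADDAT_2| between two time delays."""
    if p1.residue_ids != p2.residue_ids:
        raise ValueError("profiles cover different residue lists")
    return IADDATProfile(residue_ids=list(p1.residue_ids),
                         values=np.abs(p1.values - p2.values))


# ---------------------------------------------------------------------------
# real-space correlation
# ---------------------------------------------------------------------------

def rscc(g1: DensityGrid, g2: DensityGrid, threshold: float = 0.04) -> float | None:
    """Pearson correlation of two maps after zeroing sub-threshold voxels.

    Voxels with |rho| < threshold are set to zero independently in each
    map; the correlation runs over all voxels (no flattening with
    distance from a model). Returns None when either thresholded map has
    zero variance (the correlation is undefined).
    """
    if g1.shape != g2.shape:
        raise ValueError(f"grid dimensions differ: {g1.shape} vs {g2.shape}")
    if not g1.cell.isclose(g2.cell, rel_tol=5e-3):
        raise ValueError("grid cells disagree")
    a = np.where(np.abs(g1.values) >= threshold, g1.values, 0.0).ravel()
    b = np.where(np.abs(g2.values) >= threshold, g2.values, 0.0).ravel()
    if a.std() == 0.0 or b.std() == 0.0:
        logger.warning("thresholded map has zero variance; RSCC undefined")
        return None
    return float(np.corrcoef(a, b)[0, 1])


def rscc_matrix(grids: dict[str, DensityGrid], threshold: float = 0.04) -> pd.DataFrame:
    """Pairwise RSCC table over a named collection of maps."""
    names = list(grids)
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            r = rscc(grids[a], grids[b], threshold)
            out.loc[a, b] = out.loc[b, a] = np.nan if r is None else r
    return out
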