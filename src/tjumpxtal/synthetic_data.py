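"""Synthetic crystals, structure factors and solvent-scatter shots.

The generator produces toy datasets with the statistical structure the
downstream analysis assumes, so every stage can be exercised end to end:

* a small P1 "protein" of a few pseudo-residues, with a ground and an
  excited conformation that differ by a rigid displacement of a loop
  subset and by a global B-factor scale;
* structure factors by direct summation over atoms, with bundled
  Gaussian form factors;
* interleaved light/dark1/dark2 amplitude sets with independent Gaussian
  noise and truthful sigma columns, the mixing done on complex structure
  factors, |F_light| = |(1-f) F_ground + f F_excited|;
* per-shot solvent-scatter curves with a temperature-dependent additive
  component on the pumped shots, per-shot scale jitter and noise, on the
  light/dark1/dark2 interleaving pattern;
* radially symmetric detector images with Bragg-like spike pixels, for
  testing the azimuthal averaging.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from tjumpxtal.core_model import Atom, CrystalModel, ReflectionSet, UnitCell
from tjumpxtal.formfactors import form_factor, supported_elements
from tjumpxtal.scatter_svd import QCalibration, ScatterCurve

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Parameters of the toy two-state crystal.

    Defaults describe the reference study conditions used throughout the
    tests: a small excited-state fraction (f = 0.10), a 0.5 Angstrom loop
    displacement, modest B-factors and 2% amplitude noise.
    """

    n_residues: int = 8
    cell: UnitCell = field(default_factory=lambda: UnitCell(16.0, 18.0, 14.0))
    d_min: float = 1.6
    excited_fraction: float = 0.10
    displacement: float = 0.5
    b_ground: float = 10.0
    b_scale: float = 1.0
    noise_frac: float = 0.02
    seed: int = 0
    loop_residues: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.excited_fraction <= 1.0):
            raise ValueError("excited_fraction outside [0, 1]")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.noise_frac < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.n_residues < 2:
            raise ValueError("need at least 2 pseudo-residues")
        if self.loop_residues is None:
            mid = self.n_residues // 2
            self.loop_residues = (mid, mid + 1) if mid + 1 <= self.n_residues else (mid,)


@dataclass
class ScatterShotSpec:
    """Parameters of the per-shot solvent-scatter simulation.

    The pumped ("light") shots carry an additive difference component on
    top of the water-like base curve — the signature of the solvent
    temperature change. Shots follow the repeating light/dark1/dark2
    interleaving of the pump laser running at a third of the X-ray rate.
    ``noise_level`` and ``diff_amplitude`` are in the same (arbitrary)
    intensity units as the base curve, whose peak is 1.
    """

    n_shots: int = 300
    q: np.ndarray = field(default_factory=lambda: np.linspace(0.9, 2.8, 191))
    diff_amplitude: float = 0.01
    scale_jitter: float = 0.01
    noise_level: float = 0.002
    seed: int = 0
    base: np.ndarray | None = None
    diff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.q[0] > 1.0 or self.q[-1] < 2.7:
            raise ValueError("q grid must cover at least 1.0-2.7 inverse Angstrom")
        if self.n_shots % 3 != 0:
            raise ValueError("n_shots must be divisible by 3 (light/dark1/dark2 pattern)")
        if self.base is None:
            self.base = water_like_curve(self.q)
        if self.diff is None:
            self.diff = self.diff_amplitude * tjump_difference_shape(self.q)


def water_like_curve(q: np.ndarray) -> np.ndarray:
    """Smooth stand-in for the water scattering peak near q = 2 A^-1."""
    return np.exp(-((q - 2.0) ** 2) / (2 * 0.35 ** 2)) + 0.25 + 0.05 * (q - 2.0)


def tjump_difference_shape(q: np.ndarray) -> np.ndarray:
    """Unit-amplitude temperature signature: antisymmetric about 2.0 A^-1.

    Heating shifts the water peak to higher q, so the light-dark
    difference looks like the derivative of the peak. The exact shape is
    arbitrary for testing purposes; any smooth odd-about-2.0 curve works.
    """
    x = (q - 2.0) / 0.25
    d = x * np.exp(-0.5 * x * x)
    return d / np.max(np.abs(d))


# ---------------------------------------------------------------------------
# toy crystal models
# ---------------------------------------------------------------------------

_BACKBONE = (
    ("N", "N", np.array([-0.45, 0.7, 0.0])),
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("C", "C", np.array([1.0, 0.4, 0.5])),
    ("O", "O", np.array([1.4, 1.3, -0.2])),
)


def make_toy_model(spec: SyntheticSpec) -> tuple[CrystalModel, CrystalModel]:
    """Build ground and excited conformations of a toy P1 crystal.

    Pseudo-residues of four atoms each (N, CA, C, O) sit on a jittered
    helical path through the cell. The excited model displaces the
    designated loop residues by exactly ``spec.displacement`` Angstrom
    along a fixed direction and multiplies every B-factor by
    ``spec.b_scale``. Both models share topology and are deterministic
    under the seed.
    """
    if spec.displacement > min(spec.cell.a, spec.cell.b, spec.cell.c) / 4:
        raise ValueError(
            "displacement exceeds a quarter of the smallest cell edge; "
            "periodic wrap-around would alias the two conformations"
        )
    rng = np.random.default_rng(spec.seed)
    cell = spec.cell
    orth = cell.orthogonalization_matrix()
    frac_of = np.linalg.inv(orth)

    # helical path through the cell interior, in Cartesian Angstrom
    n = spec.n_residues
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    centre = orth @ np.array([0.5, 0.5, 0.5])
    radius = 0.28 * min(cell.a, cell.b)
    path = np.stack([
        centre[0] + radius * np.cos(t),
        centre[1] + radius * np.sin(t),
        centre[2] + (t / (2 * math.pi) - 0.5) * 0.5 * cell.c,
    ], axis=1)
    path += rng.normal(scale=0.15, size=path.shape)

    atoms: list[Atom] = []
    for i in range(n):
        jitter = rng.normal(scale=0.05, size=(len(_BACKBONE), 3))
        for j, (name, elem, off) in enumerate(_BACKBONE):
            cart = path[i] + off + jitter[j]
            atoms.append(Atom(element=elem, frac=frac_of @ cart,
                              occupancy=1.0, b=spec.b_ground,
                              resnum=i + 1, resname="GLY", chain="A", name=name))
    ground = CrystalModel(atoms=atoms, cell=cell, spacegroup="P 1")

    direction = np.array([1.0, 1.0, 0.5])
    direction /= np.linalg.norm(direction)
    shift_cart = spec.displacement * direction
    shift_frac = frac_of @ shift_cart
    excited_frac = ground.frac_coords.copy()
    for k, at in enumerate(ground.atoms):
        if at.resnum in spec.loop_residues:
            excited_frac[k] += shift_frac
    excited = ground.with_coords(excited_frac).with_bscale(spec.b_scale)
    return ground, excited


# ---------------------------------------------------------------------------
# structure factors by direct summation
# ---------------------------------------------------------------------------

def generate_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """Unique half-sphere of Miller indices with d >= d_min (P1, no (000)).

    The asymmetric set keeps h > 0, or h = 0 and k > 0, or h = k = 0 and
    l > 0; the Friedel mates are implied.
    """
    hmax = int(math.floor(cell.a / d_min)) + 1
    kmax = int(math.floor(cell.b / d_min)) + 1
    lmax = int(math.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    half = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    hkl = hkl[half]
    d = cell.d_spacing(hkl)
    return hkl[d >= d_min]


def structure_factors_complex(model: CrystalModel, hkl: np.ndarray) -> np.ndarray:
    """Complex F(h) by direct summation over atoms.

    F(h) = sum_atoms occ * f_elem(s) * exp(-B s^2 / 4) * exp(2 pi i h.x)
    with s = 1/d. Unknown elements raise, listing the supported set.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    d = model.cell.d_spacing(hkl)
    with np.errstate(divide="ignore"):
        stol2 = np.where(np.isfinite(d), 1.0 / (4.0 * d * d), 0.0)
    F = np.zeros(len(hkl), dtype=complex)
    phases = np.exp(2j * np.pi * (hkl @ model.frac_coords.T))  # (n_hkl, n_atoms)
    elements = {a.element for a in model.atoms}
    for elem in elements:
        ff = form_factor(elem, stol2)  # raises for unknown elements
        sel = np.array([a.element == elem for a in model.atoms])
        occ = np.array([a.occupancy for a in model.atoms])[sel]
        b = np.array([a.b for a in model.atoms])[sel]
        dw = np.exp(-np.outer(stol2, b))  # (n_hkl, n_sel)
        F += ff * np.einsum("j,ij,ij->i", occ, dw, phases[:, sel])
    return F


def calc_structure_factors(model: CrystalModel, d_min: float,
                           label: str = "custom") -> ReflectionSet:
    """Amplitudes and phases on the unique half-sphere down to ``d_min``."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hkl = generate_hkl(model.cell, d_min)
    F = structure_factors_complex(model, hkl)
    return ReflectionSet(hkl=hkl, f=np.abs(F), sigf=np.zeros(len(hkl)),
                         phase=np.degrees(np.angle(F)), cell=model.cell,
                         d_min=d_min, label=label)


# ---------------------------------------------------------------------------
# interleaved T-jump amplitude datasets
# ---------------------------------------------------------------------------

@dataclass
class TjumpDataset:
    """Simulated merged amplitude sets for one pump-probe delay."""

    f_dark1: ReflectionSet
    f_dark2: ReflectionSet
    f_t: ReflectionSet
    ground: CrystalModel
    excited: CrystalModel
    f_true_dark: np.ndarray
    f_true_light: np.ndarray


def simulate_tjump_dataset(spec: SyntheticSpec) -> TjumpDataset:
    """Simulate the interleaved light/dark1/dark2 amplitude sets.

    The light state is a crystal-averaged mixture: complex
    F_light = (1-f) F_ground + f F_excited, amplitudes taken afterwards.
    dark1 and dark2 are independent noisy draws around the ground-state
    amplitudes; F_t is a noisy draw around the mixed amplitudes. Noise is
    Gaussian with sigma = noise_frac * F_true per reflection, and the
    sigma columns store that truth. Phases attached to the dark sets come
    from the ground model.
    """
    ground, excited = make_toy_model(spec)
    hkl = generate_hkl(spec.cell, spec.d_min)
    Fg = structure_factors_complex(ground, hkl)
    Fe = structure_factors_complex(excited, hkl)
    f = spec.excited_fraction
    f_true_dark = np.abs(Fg)
    f_true_light = np.abs((1.0 - f) * Fg + f * Fe)
    phase_dark = np.degrees(np.angle(Fg))

    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    sig_dark = spec.noise_frac * f_true_dark
    sig_light = spec.noise_frac * f_true_light

    def draw(rng: np.random.Generator, truth: np.ndarray, sig: np.ndarray,
             phase: np.ndarray | None, label: str) -> ReflectionSet:
        obs = np.clip(truth + rng.normal(size=truth.shape) * sig, 0.0, None)
        return ReflectionSet(hkl=hkl, f=obs, sigf=sig, phase=phase,
                             cell=spec.cell, d_min=spec.d_min, label=label)

    return TjumpDataset(
        f_dark1=draw(rngs[0], f_true_dark, sig_dark, phase_dark, "dark1"),
        f_dark2=draw(rngs[1], f_true_dark, sig_dark, phase_dark, "dark2"),
        f_t=draw(rngs[2], f_true_light, sig_light, None, "t20ns"),
        ground=ground, excited=excited,
        f_true_dark=f_true_dark, f_true_light=f_true_light,
    )


# ---------------------------------------------------------------------------
# solvent-scatter shots and detector images
# ---------------------------------------------------------------------------

_PATTERN = ("light", "dark1", "dark2")


def simulate_scatter_shots(spec: ScatterShotSpec) -> list[ScatterCurve]:
    """Simulate interleaved per-shot scatter curves with true labels.

    Light shots: scale * (base + diff) + noise; dark shots:
    scale * base + noise. The simulated laser diode reports the truth.
    """
    rng = np.random.default_rng(spec.seed)
    shots: list[ScatterCurve] = []
    for i in range(spec.n_shots):
        label = _PATTERN[i % 3]
        scale = 1.0 + spec.scale_jitter * rng.normal()
        signal = spec.base + spec.diff if label == "light" else spec.base
        intensity = scale * signal + spec.noise_level * rng.normal(size=spec.q.shape)
        shots.append(ScatterCurve(q=spec.q.copy(), intensity=intensity,
                                  shot_id=i, diode_flag=(label == "light"),
                                  true_label=label))
    return shots


def render_detector_image(
    curve: ScatterCurve,
    n_spikes: int = 0,
    seed: int = 0,
    shape: tuple[int, int] = (192, 192),
) -> tuple[np.ndarray, tuple[float, float], QCalibration]:
    """Render a radially symmetric detector image from a 1D curve.

    The azimuthal average of the image reproduces the curve up to pixel
    quantization. ``n_spikes`` isolated pixels are set to 100x the local
    value, emulating Bragg peaks punching through the solvent scatter.
    Returns (image, beam centre, q calibration).
    """
    rng = np.random.default_rng(seed)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    rmax = min(cy, cx)
    cal = QCalibration(q0=curve.q[0], slope=(curve.q[-1] - curve.q[0]) / rmax)
    yy, xx = np.indices(shape)
    r = np.hypot(yy - cy, xx - cx)
    q = cal.q_of_radius(r)
    image = np.interp(q, curve.q, curve.intensity)
    if n_spikes:
        ys = rng.integers(0, shape[0], size=n_spikes)
        xs = rng.integers(0, shape[1], size=n_spikes)
        image[ys, xs] *= 100.0
    return image, (cy, cx), cal
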