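"""Domain types and file I/O: unit cells, atomic models, reflection sets.

Conventions used throughout the package:

* fractional coordinates are the internal representation for atoms;
  Cartesian conversion is an explicit function of the unit cell;
* reflection sets are condition-labelled (``laser_off``, ``dark1``,
  ``dark2``, ``t20ns``, ...) so that light/dark pairing is explicit,
  never positional;
* synthetic work is done in P1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

logger = logging.getLogger(__name__)

CONDITION_LABELS = ("laser_off", "dark1", "dark2", "t20ns", "t20us", "t200us", "custom")


# ---------------------------------------------------------------------------
# Unit cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"cell lengths must be positive, got {self.a, self.b, self.c}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not (0.0 < ang < 180.0):
                raise ValueError(f"cell angle {name}={ang} outside (0, 180)")
        if self.volume <= 0:
            raise ValueError("degenerate cell: non-positive volume")

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to Cartesian coordinates (PDB convention)."""
        m = self.to_gemmi().orth.mat
        return np.array(m.tolist(), dtype=float)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d(h,k,l) in Angstrom for an (n, 3) integer index array."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # |h·A*|: reciprocal metric via the inverse orthogonalization matrix
        frac = np.linalg.inv(self.orthogonalization_matrix())  # Cartesian -> fractional
        s_vec = hkl @ frac  # reciprocal-space vector in 1/Angstrom
        s = np.linalg.norm(s_vec, axis=1)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / s, np.inf)

    def isclose(self, other: "UnitCell", rel_tol: float = 5e-3) -> bool:
        mine = (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        theirs = (other.a, other.b, other.c, other.alpha, other.beta, other.gamma)
        return all(math.isclose(x, y, rel_tol=rel_tol) for x, y in zip(mine, theirs))


# ---------------------------------------------------------------------------
# Atomic model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom with fractional coordinates.

    ``frac`` is a length-3 float array; ``b`` is the isotropic displacement
    parameter in Angstrom^2.
    """

    element: str
    frac: np.ndarray
    occupancy: float = 1.0
    b: float = 0.0
    altloc: str = ""
    resnum: int = 1
    resname: str = "ALA"
    chain: str = "A"
    is_water: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)
        if self.frac.shape != (3,):
            raise ValueError("fractional coordinate must be a 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b < 0:
            raise ValueError(f"negative B-factor {self.b}")
        if not self.name:
            self.name = self.element


@dataclass
class CrystalModel:
    """Atomic model: atoms with fractional coordinates, cell and symmetry."""

    atoms: list[Atom]
    cell: UnitCell
    spacegroup: str = "P 1"

    def __post_init__(self) -> None:
        self._check_altloc_occupancies()

    def _check_altloc_occupancies(self) -> None:
        groups: dict[tuple, float] = {}
        for at in self.atoms:
            if at.altloc:
                key = (at.chain, at.resnum, at.name)
                groups[key] = groups.get(key, 0.0) + at.occupancy
        for key, total in groups.items():
            if total > 1.0 + 1e-6:
                raise ValueError(f"altloc occupancies at site {key} sum to {total} > 1")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def frac_coords(self) -> np.ndarray:
        return np.array([a.frac for a in self.atoms], dtype=float)

    @property
    def cart_coords(self) -> np.ndarray:
        return self.frac_coords @ self.cell.orthogonalization_matrix().T

    @property
    def residue_ids(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, resnum) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for at in self.atoms:
            seen.setdefault((at.chain, at.resnum), None)
        return list(seen)

    def select(self, *, waters: bool | None = None, name: str | None = None) -> "CrystalModel":
        """Return a sub-model filtered on water flag and/or atom name."""
        picked = [
            a for a in self.atoms
            if (waters is None or a.is_water == waters)
            and (name is None or a.name.strip() == name)
        ]
        return CrystalModel(atoms=picked, cell=self.cell, spacegroup=self.spacegroup)

    def with_coords(self, frac: np.ndarray) -> "CrystalModel":
        frac = np.asarray(frac, dtype=float)
        if frac.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        new_atoms = [replace(a, frac=frac[i].copy()) for i, a in enumerate(self.atoms)]
        return CrystalModel(atoms=new_atoms, cell=self.cell, spacegroup=self.spacegroup)

    def with_bscale(self, scale: float) -> "CrystalModel":
        """Return a copy with every isotropic B multiplied by ``scale``."""
        new_atoms = [replace(a, b=a.b * scale) for a in self.atoms]
        return CrystalModel(atoms=new_atoms, cell=self.cell, spacegroup=self.spacegroup)


WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_model(path: str | Path) -> CrystalModel:
    """Read a PDB file into a :class:`CrystalModel`.

    Coordinates are converted to fractional using the file's CRYST1 cell.
    Waters are flagged by residue name (HOH/WAT/DOD). Raises ``ValueError``
    if the file has no CRYST1 record or no atoms.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if st.cell.a == 0 or not st.cell.is_crystal():
        raise ValueError(f"{path}: no usable CRYST1 record (cell undefined)")
    cell = UnitCell.from_gemmi(st.cell)
    frac_mat = np.linalg.inv(cell.orthogonalization_matrix())
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    cart = np.array([at.pos.x, at.pos.y, at.pos.z])
                    atoms.append(Atom(
                        element=at.element.name,
                        frac=frac_mat @ cart,
                        occupancy=at.occ,
                        b=at.b_iso,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        resnum=res.seqid.num,
                        resname=res.name,
                        chain=chain.name,
                        is_water=res.name in WATER_RESNAMES,
                        name=at.name,
                    ))
        break  # first model only
    if not atoms:
        raise ValueError(f"{path}: no atoms found")
    sg = st.spacegroup_hm or "P 1"
    return CrystalModel(atoms=atoms, cell=cell, spacegroup=sg)


def write_model(model: CrystalModel, path: str | Path) -> None:
    """Write a :class:`CrystalModel` as a PDB file (ATOM/HETATM + CRYST1)."""
    st = gemmi.Structure()
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    orth = model.cell.orthogonalization_matrix()
    chains: dict[str, gemmi.Chain] = {}
    for at in model.atoms:
        ch = chains.get(at.chain)
        if ch is None:
            ch = gemmi.Chain(at.chain)
            chains[at.chain] = ch
        res = None
        if len(ch) > 0:
            last = ch[len(ch) - 1]
            if last.seqid.num == at.resnum and last.name == at.resname:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = at.resname
            res.seqid = gemmi.SeqId(at.resnum, " ")
            res.het_flag = "H" if at.is_water else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
        ga = gemmi.Atom()
        ga.name = at.name
        ga.element = gemmi.Element(at.element)
        cart = orth @ at.frac
        ga.pos = gemmi.Position(*cart)
        ga.occ = at.occupancy
        ga.b_iso = at.b
        ga.altloc = at.altloc if at.altloc else "\x00"
        res.add_atom(ga)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Reflection data
# ---------------------------------------------------------------------------

@dataclass
class ReflectionSet:
    """Merged structure-factor amplitudes |F| with uncertainties.

    ``hkl`` is an (n, 3) integer array of Miller indices, ``f`` and
    ``sigf`` are amplitudes and sigmas in electrons, ``phase`` (optional)
    holds phases in degrees. The set carries its unit cell, resolution
    limit and an experimental condition label so that light/dark pairing
    is explicit.
    """

    hkl: np.ndarray
    f: np.ndarray
    sigf: np.ndarray
    cell: UnitCell
    d_min: float
    phase: np.ndarray | None = None
    label: str = "custom"

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=float)
        self.sigf = np.asarray(self.sigf, dtype=float)
        n = len(self.hkl)
        if self.f.shape != (n,) or self.sigf.shape != (n,):
            raise ValueError("hkl, f, sigf length mismatch")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if self.phase.shape != (n,):
                raise ValueError("phase length mismatch")
        if np.any(self.f < 0):
            raise ValueError("negative amplitude |F|")
        if np.any(self.sigf < 0):
            raise ValueError("negative sigma")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.label not in CONDITION_LABELS:
            raise ValueError(f"unknown condition label {self.label!r}")
        # uniqueness of Miller indices
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != n:
            raise ValueError("duplicate Miller indices in reflection set")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "H": self.hkl[:, 0], "K": self.hkl[:, 1], "L": self.hkl[:, 2],
            "F": self.f, "SIGF": self.sigf,
        })
        if self.phase is not None:
            df["PHI"] = self.phase
        return df

    # -- CSV dialect: header H,K,L,F,SIGF[,PHI]; phases in degrees ---------

    def to_csv(self, path: str | Path) -> None:
        """Write the documented CSV dialect with the cell in a comment header."""
        path = Path(path)
        c = self.cell
        with open(path, "w") as fh:
            fh.write(f"# cell {c.a:.6f} {c.b:.6f} {c.c:.6f} "
                     f"{c.alpha:.4f} {c.beta:.4f} {c.gamma:.4f}\n")
            fh.write(f"# d_min {self.d_min:.6f}\n")
            fh.write(f"# label {self.label}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReflectionSet":
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    parts = line[1:].split()
                    meta[parts[0]] = parts[1:]
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh)
        for col in ("H", "K", "L", "F", "SIGF"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col}")
        if "cell" not in meta:
            raise ValueError(f"{path}: missing '# cell' header line")
        cell = UnitCell(*map(float, meta["cell"]))
        d_min = float(meta["d_min"][0]) if "d_min" in meta else float(
            cell.d_spacing(df[["H", "K", "L"]].to_numpy()).min())
        label = meta["label"][0] if "label" in meta else "custom"
        return cls(
            hkl=df[["H", "K", "L"]].to_numpy(),
            f=df["F"].to_numpy(), sigf=df["SIGF"].to_numpy(),
            phase=df["PHI"].to_numpy() if "PHI" in df.columns else None,
            cell=cell, d_min=d_min, label=label,
        )

    # -- MTZ via gemmi -----------------------------------------------------

    def to_mtz(self, path: str | Path) -> None:
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.SpaceGroup("P1")
        mtz.set_cell_for_all(self.cell.to_gemmi())
        mtz.add_dataset("tjumpxtal")
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
        cols = [self.hkl.astype(float), self.f[:, None], self.sigf[:, None]]
        if self.phase is not None:
            mtz.add_column("PHI", "P")
            cols.append(self.phase[:, None])
        mtz.set_data(np.hstack(cols))
        mtz.write_to_file(str(path))

    @classmethod
    def from_mtz(cls, path: str | Path, label: str = "custom") -> "ReflectionSet":
        mtz = gemmi.read_mtz_file(str(path))
        arr = np.array(mtz, copy=False)
        names = [c.label for c in mtz.columns]
        idx = {n: i for i, n in enumerate(names)}
        for col in ("H", "K", "L", "F", "SIGF"):
            if col not in idx:
                raise ValueError(f"{path}: MTZ lacks column {col}")
        hkl = arr[:, [idx["H"], idx["K"], idx["L"]]].astype(int)
        cell = UnitCell.from_gemmi(mtz.cell)
        phase = arr[:, idx["PHI"]] if "PHI" in idx else None
        d_min = float(cell.d_spacing(hkl).min())
        return cls(hkl=hkl, f=arr[:, idx["F"]], sigf=arr[:, idx["SIGF"]],
                   phase=phase, cell=cell, d_min=d_min, label=label)


# ---------------------------------------------------------------------------
# Descriptive statistics (unit-cell expansion, B-factor trends)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellStatsResult:
    """Mean axis length with a 95% confidence interval half-width."""

    mean: float
    ci95_half_width: float
    n: int


def mean_bfactor(model: CrystalModel, include_waters: bool = False) -> float:
    """Unweighted arithmetic mean of isotropic B over the selected atoms.

    Waters are excluded by default, mirroring the water exclusion used in
    the difference-density integration; pass ``include_waters=True`` to
    average over everything.
    """
    bs = [a.b for a in model.atoms if include_waters or not a.is_water]
    if not bs:
        raise ValueError("no atoms left after water filtering")
    return float(np.mean(bs))


def cell_stats(cells: Sequence[UnitCell], axis: str = "a") -> CellStatsResult:
    """Mean and 95% CI of one cell-axis length over a set of unit cells.

    Uses the normal approximation (mean +/- 1.96 sd/sqrt(n)) for n >= 30
    and the Student-t critical value below that.
    """
    if axis not in ("a", "b", "c"):
        raise ValueError(f"axis must be one of a/b/c, got {axis!r}")
    vals = np.array([getattr(c, axis) for c in cells], dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 cells for a confidence interval")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    crit = 1.959963984540054 if n >= 30 else float(_scipy_stats.t.ppf(0.975, n - 1))
    return CellStatsResult(mean=mean, ci95_half_width=crit * sd / math.sqrt(n), n=n)
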