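"""Anisotropic network model on C-alpha nodes.

The protein is reduced to one node per residue (the C-alpha), connected
by identical harmonic springs (force constant gamma) to every neighbour
within a distance cutoff. The 3n x 3n Hessian has, for each connected
pair, the off-diagonal super-element -gamma * d d^T / |d|^2 built from
the equilibrium separation d; diagonal blocks are the negative sums of a
node's off-diagonal blocks. Its eigen-decomposition yields 6 zero modes
(rigid translations/rotations) and 3n-6 vibrational modes; the
lowest-frequency modes describe collective motions. Modes are combined
into a single displacement field by weighting each with sqrt(1/lambda),
emphasizing the softest directions, and the combined vector can be
projected onto the atomic model for comparison with observed loop
displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from tjumpxtal.core_model import CrystalModel

NULL_MODE_TOL = 1e-8


@dataclass
class ANMModel:
    """ANM Hessian and its non-rigid eigenmodes.

    ``eigvals`` are the nonzero eigenvalues ascending; ``eigvecs`` holds
    the matching unit eigenvectors as columns of a (3n, n_modes) array,
    sign-fixed so each vector's largest-magnitude component is positive.
    """

    coords: np.ndarray
    cutoff: float
    gamma: float
    hessian: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    n_null: int

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def fluctuations(self) -> np.ndarray:
        """Per-node squared fluctuation profile: sum_i |V_i(node)|^2 / lambda_i."""
        contrib = self.eigvecs ** 2 / self.eigvals  # (3n, m)
        per_coord = contrib.sum(axis=1)
        return per_coord.reshape(-1, 3).sum(axis=1)


@dataclass
class CombinedMode:
    """Single displacement field combining the softest modes.

    V_total = sum_i sqrt(1/lambda_i) V_i over the n lowest nonzero modes.
    """

    vector: np.ndarray            # (3n,)
    weights: np.ndarray           # sqrt(1/lambda_i)

    @property
    def per_node(self) -> np.ndarray:
        return self.vector.reshape(-1, 3)


def build_anm(calphas: np.ndarray, cutoff: float = 15.0, gamma: float = 1.0) -> ANMModel:
    """Build and diagonalize the ANM Hessian for a set of node coordinates.

    Raises if the contact network at the given cutoff is disconnected
    (more than 6 null modes), naming the number of components.
    """
    coords = np.asarray(calphas, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if cutoff <= 0 or gamma <= 0:
        raise ValueError("cutoff and gamma must be positive")

    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    contact = (dist2 <= cutoff ** 2) & ~np.eye(n, dtype=bool)

    n_comp, _ = connected_components(csr_matrix(contact), directed=False)
    if n_comp > 1:
        raise ValueError(f"contact network is disconnected ({n_comp} components)")

    hess = np.zeros((3 * n, 3 * n))
    ii, jj = np.where(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        d = diff[i, j]
        block = -gamma * np.outer(d, d) / dist2[i, j]
        hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block

    eigvals, eigvecs = np.linalg.eigh(hess)
    tol = NULL_MODE_TOL * max(eigvals[-1], 1.0)
    null = eigvals < tol
    n_null = int(null.sum())
    if n_null > 6:
        raise ValueError(
            f"{n_null} null modes found; the network is effectively disconnected"
        )
    vals = eigvals[~null]
    vecs = eigvecs[:, ~null]
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] *= -1.0
    return ANMModel(coords=coords, cutoff=cutoff, gamma=gamma, hessian=hess,
                    eigvals=vals, eigvecs=vecs, n_null=n_null)


def combine_modes(model: ANMModel, n: int = 20) -> CombinedMode:
    """Combine the n lowest-frequency nonzero modes, each scaled by sqrt(1/lambda)."""
    if n < 1:
        raise ValueError("need at least one mode")
    if model.eigvals.size < n:
        raise ValueError(
            f"requested {n} modes but only {model.eigvals.size} nonzero modes exist"
        )
    w = np.sqrt(1.0 / model.eigvals[:n])
    vec = model.eigvecs[:, :n] @ w
    return CombinedMode(vector=vec, weights=w)


def extract_calphas(model: CrystalModel) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """C-alpha Cartesian coordinates and their residue identifiers."""
    ca = model.select(name="CA")
    if len(ca) == 0:
        raise ValueError("model has no CA atoms")
    return ca.cart_coords, ca.residue_ids


def project_coords(model: CrystalModel, mode: CombinedMode,
                   amplitude: float) -> tuple[CrystalModel, pd.DataFrame]:
    """Displace a model along the combined mode.

    Every atom of residue r moves by amplitude times that residue's node
    vector; the per-residue displacement vectors are returned as a table
    for rendering (arrows between C-alpha positions).
    """
    res_ids = model.residue_ids
    per_node = mode.per_node
    if len(res_ids) != len(per_node):
        raise ValueError(
            f"model has {len(res_ids)} residues but the mode has {len(per_node)} nodes"
        )
    res_index = {rid: i for i, rid in enumerate(res_ids)}
    orth = model.cell.orthogonalization_matrix()
    frac_of = np.linalg.inv(orth)
    frac = model.frac_coords.copy()
    for k, at in enumerate(model.atoms):
        dv = amplitude * per_node[res_index[(at.chain, at.resnum)]]
        frac[k] += frac_of @ dv
    displaced = model.with_coords(frac)
    table = pd.DataFrame({
        "chain": [c for c, _ in res_ids],
        "resnum": [r for _, r in res_ids],
        "dx": amplitude * per_node[:, 0],
        "dy": amplitude * per_node[:, 1],
        "dz": amplitude * per_node[:, 2],
    })
    return displaced, table
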