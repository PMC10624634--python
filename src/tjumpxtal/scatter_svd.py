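"""Pump-event detection from solvent scattering.

The analysis detects the laser-induced temperature jump directly from the
diffuse solvent scatter recorded on every shot: each detector image is
azimuthally averaged with a sliding median filter (suppressing Bragg
contributions), the resulting 1D curves are least-squares scaled to a
common reference over 2.0-2.5 inverse Angstrom, stacked into a matrix
restricted to 1.0-2.7 inverse Angstrom, and decomposed by SVD. The loading
of the temperature-dependent basis curve (the second right singular
vector, v1) separates pumped from dark shots; the split is validated
against the laser diode record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ScatterCurve:
    """One azimuthally averaged scattering curve.

    ``diode_flag`` is the recorded laser-diode state (pump on/off);
    ``true_label`` is only populated by the synthetic generator.
    """

    q: np.ndarray
    intensity: np.ndarray
    shot_id: int = 0
    diode_flag: bool = False
    true_label: str | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape or self.q.ndim != 1:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")


@dataclass
class ScatterConfig:
    """Tunable settings for the scatter pipeline.

    ``median_window`` is in q bins and is forced odd (>= 3);
    the scaling mask and analysis range are in inverse Angstrom.
    """

    median_window: int = 15
    scale_range: tuple[float, float] = (2.0, 2.5)
    analysis_range: tuple[float, float] = (1.0, 2.7)

    def __post_init__(self) -> None:
        w = int(self.median_window)
        if w < 3:
            w = 3
        if w % 2 == 0:
            w += 1
        self.median_window = w


@dataclass
class ScatterMatrix:
    """Scaled curves stacked row-wise, restricted to the analysis q range."""

    q: np.ndarray
    matrix: np.ndarray           # (n_shots, n_q)
    scale_factors: np.ndarray
    shot_ids: np.ndarray
    diode_flags: np.ndarray
    true_labels: list | None = None
    culled_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class SVDResult:
    """Thin SVD of a scatter matrix with a deterministic sign convention.

    Rows of ``v`` are basis curves v_n; columns of ``u`` are per-shot
    loadings u_n. Each v_n is flipped so its largest-magnitude entry is
    positive, with u_n flipped accordingly.
    """

    u: np.ndarray                # (n_shots, k)
    s: np.ndarray                # (k,)
    v: np.ndarray                # (k, n_q)
    q: np.ndarray
    shot_ids: np.ndarray
    diode_flags: np.ndarray
    true_labels: list | None = None


@dataclass
class ClassificationResult:
    """Two-class split of one u-component with diode-flag validation."""

    labels: np.ndarray            # "light" / "dark" per shot
    u_values: np.ndarray
    threshold: float
    diode_agreement: float
    confusion: pd.DataFrame
    degenerate: bool
    shot_ids: np.ndarray


# ---------------------------------------------------------------------------
# azimuthal averaging
# ---------------------------------------------------------------------------

def sliding_median(values: np.ndarray, window: int) -> np.ndarray:
    """Sliding median with a symmetric window that shrinks near the edges.

    NaN entries (empty bins) are ignored inside each window and preserved
    in place in the output.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        win = values[i - k:i + k + 1]
        good = win[np.isfinite(win)]
        out[i] = np.median(good) if good.size else np.nan
    # keep genuinely empty bins flagged missing
    out[~np.isfinite(values)] = np.nan
    return out


@dataclass(frozen=True)
class QCalibration:
    """Affine pixel-radius to q mapping: q(r) = q0 + slope * r."""

    q0: float
    slope: float

    def q_of_radius(self, r: np.ndarray) -> np.ndarray:
        return self.q0 + self.slope * np.asarray(r, dtype=float)


def azimuthal_average(
    image: np.ndarray,
    centre: tuple[float, float],
    calibration: QCalibration,
    config: ScatterConfig | None = None,
    q_grid: np.ndarray | None = None,
    n_bins: int = 150,
    shot_id: int = 0,
    diode_flag: bool = False,
) -> ScatterCurve:
    """Median-filtered azimuthal average of a 2D detector image.

    Pixels are binned by q; each bin takes the mean intensity and the bin
    series is then smoothed with the sliding median filter, which removes
    isolated Bragg-like outliers while preserving the smooth solvent
    scatter. Empty bins come back as NaN, never zero.
    """
    config = config or ScatterConfig()
    image = np.asarray(image, dtype=float)
    cy, cx = centre
    if not (0 <= cy < image.shape[0] and 0 <= cx < image.shape[1]):
        raise ValueError("beam centre outside the image")
    yy, xx = np.indices(image.shape)
    r = np.hypot(yy - cy, xx - cx)
    q = calibration.q_of_radius(r).ravel()
    vals = image.ravel()

    if q_grid is not None:
        q_grid = np.asarray(q_grid, dtype=float)
        edges = np.concatenate((
            [q_grid[0] - 0.5 * (q_grid[1] - q_grid[0])],
            0.5 * (q_grid[1:] + q_grid[:-1]),
            [q_grid[-1] + 0.5 * (q_grid[-1] - q_grid[-2])],
        ))
        centres = q_grid
    else:
        edges = np.linspace(q.min(), q.max(), n_bins + 1)
        centres = 0.5 * (edges[1:] + edges[:-1])

    idx = np.digitize(q, edges) - 1
    ok = (idx >= 0) & (idx < len(centres))
    sums = np.bincount(idx[ok], weights=vals[ok], minlength=len(centres))
    counts = np.bincount(idx[ok], minlength=len(centres))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    filtered = sliding_median(means, config.median_window)
    return ScatterCurve(q=centres, intensity=filtered,
                        shot_id=shot_id, diode_flag=diode_flag)


# ---------------------------------------------------------------------------
# scaling and SVD
# ---------------------------------------------------------------------------

def scale_curves(curves: list[ScatterCurve], config: ScatterConfig | None = None,
                 cull: bool = True) -> ScatterMatrix:
    """Least-squares scale every curve to the ensemble mean over the scale mask.

    Each curve is multiplied by the scalar minimizing the squared deviation
    from the mean curve over ``config.scale_range``; rows of the output
    matrix are restricted to ``config.analysis_range``. Curves whose scale
    factor is more than 5 median absolute deviations from the median factor
    are dropped as collection anomalies (jet clogs and the like).
    """
    config = config or ScatterConfig()
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to scale")
    q = curves[0].q
    for c in curves[1:]:
        if c.q.shape != q.shape or not np.array_equal(c.q, q):
            raise ValueError(
                f"curve {c.shot_id} is on a different q grid; no silent interpolation"
            )
    lo, hi = config.scale_range
    mask = (q >= lo) & (q <= hi)
    if not mask.any():
        raise ValueError("scaling range contains no q bins")
    raw = np.stack([c.intensity for c in curves])
    ref = raw.mean(axis=0)
    num = raw[:, mask] @ ref[mask]
    den = np.einsum("ij,ij->i", raw[:, mask], raw[:, mask])
    factors = num / den

    keep = np.ones(len(curves), dtype=bool)
    if cull:
        med = np.median(factors)
        mad = np.median(np.abs(factors - med))
        if mad > 0:
            keep = np.abs(factors - med) <= 5.0 * mad
            if not keep.all():
                logger.info("culled %d anomalous curves", (~keep).sum())

    alo, ahi = config.analysis_range
    amask = (q >= alo) & (q <= ahi)
    if not amask.any():
        raise ValueError("analysis range contains no q bins")
    scaled = (factors[:, None] * raw)[np.ix_(keep, amask)]
    ids = np.array([c.shot_id for c in curves])
    flags = np.array([c.diode_flag for c in curves])
    labels = [c.true_label for c in curves]
    labels_kept = [l for l, k in zip(labels, keep) if k]
    return ScatterMatrix(
        q=q[amask], matrix=scaled, scale_factors=factors[keep],
        shot_ids=ids[keep], diode_flags=flags[keep],
        true_labels=labels_kept if any(l is not None for l in labels_kept) else None,
        culled_ids=ids[~keep],
    )


def svd_curves(sm: ScatterMatrix) -> SVDResult:
    """Thin SVD of the scaled curve matrix with sign fixing.

    Raises on non-finite entries, naming the offending row.
    """
    m = sm.matrix
    if m.shape[0] < 2:
        raise ValueError("need at least 2 curves for SVD")
    bad = ~np.isfinite(m).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite entries in rows {np.where(bad)[0].tolist()}")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    # sign convention: largest-magnitude entry of each basis curve positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    return SVDResult(u=u, s=s, v=vt, q=sm.q, shot_ids=sm.shot_ids,
                     diode_flags=sm.diode_flags, true_labels=sm.true_labels)


def classify_shots(svd: SVDResult, component: int = 1) -> ClassificationResult:
    """Split shots into pumped/dark classes from one u-component.

    Initial classes come from the sign of the loading (after the SVD sign
    convention); the decision threshold is then the midpoint of the two
    class means, robust to loading offsets. The class that agrees better
    with the laser-diode record is called "light". A warning is raised
    when the two classes are separated by less than three times the
    pooled standard deviation (unimodal loadings), but the split is
    still returned.
    """
    if component >= svd.u.shape[1]:
        raise ValueError(f"component {component} not available (have {svd.u.shape[1]})")
    u = svd.u[:, component]
    pos = u > 0
    degenerate = False
    if pos.all() or (~pos).all():
        degenerate = True
        threshold = float(np.mean(u))
    else:
        m1, m0 = u[pos].mean(), u[~pos].mean()
        threshold = 0.5 * (m1 + m0)
        sd = np.sqrt(0.5 * (np.var(u[pos]) + np.var(u[~pos])))
        # a single normal split at its mean gives |m1-m0| = 2.65 x the
        # within-class sd, so only a ratio clearly above that indicates
        # two real clusters
        if sd > 0 and abs(m1 - m0) < 3.0 * sd:
            degenerate = True
    if degenerate:
        warnings.warn("degenerate split: u-component loadings look unimodal",
                      stacklevel=2)
    above = u > threshold
    flags = np.asarray(svd.diode_flags, dtype=bool)
    agree_above = np.mean(above == flags)
    if agree_above >= 0.5:
        labels = np.where(above, "light", "dark")
        agreement = float(agree_above)
    else:
        labels = np.where(above, "dark", "light")
        agreement = float(1.0 - agree_above)
    pred_light = labels == "light"
    confusion = pd.DataFrame(
        [[int(np.sum(pred_light & flags)), int(np.sum(pred_light & ~flags))],
         [int(np.sum(~pred_light & flags)), int(np.sum(~pred_light & ~flags))]],
        index=["pred_light", "pred_dark"], columns=["diode_on", "diode_off"],
    )
    return ClassificationResult(labels=labels, u_values=u, threshold=threshold,
                                diode_agreement=agreement, confusion=confusion,
                                degenerate=degenerate, shot_ids=svd.shot_ids)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def write_svd_tables(svd: SVDResult, prefix: str) -> None:
    """Write U, s, V as TSV files with the given path prefix."""
    pd.DataFrame(svd.u).to_csv(f"{prefix}_U.tsv", sep="\t", index=False)
    pd.DataFrame({"s": svd.s}).to_csv(f"{prefix}_s.tsv", sep="\t", index=False)
    vdf = pd.DataFrame(svd.v.T)
    vdf.insert(0, "q", svd.q)
    vdf.to_csv(f"{prefix}_V.tsv", sep="\t", index=False)


def write_classification_table(res: ClassificationResult, svd: SVDResult,
                               path: str) -> None:
    pd.DataFrame({
        "shot_id": res.shot_ids,
        "u1": res.u_values,
        "predicted": res.labels,
        "diode_flag": np.asarray(svd.diode_flags, dtype=bool),
    }).to_csv(path, sep="\t", index=False)
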