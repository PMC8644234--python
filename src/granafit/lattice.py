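"""2D Bravais-lattice estimation for PSII semi-crystalline arrays.

PSII supercomplexes in grana membranes can pack into ordered 2D arrays. The
centres of the PSII cores are the lattice points; the array is summarised by
a unit cell (a, b, alpha) with a >= b and alpha folded into (0, 90]
(reporting both alpha and its supplement, since either describes the same
cell), by the orientation angle phi between the a vector and the diagonal of
the C2S2 supercomplex, and — per micrograph — by the fraction of membrane
area occupied by crystalline arrays.

Fitting strategy: candidate basis vectors are the two shortest non-collinear
modes of the nearest-neighbour difference-vector distribution; the basis and
origin are then refined by least squares over integer index assignments
(points whose residual exceeds 0.3 x min(a, b) are left unassigned), and the
final basis is Lagrange-Gauss reduced so equivalent generating bases report
identical cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DomainError, NoLatticeError, ValidationError
from .traces import BinaryMask, PointSet2D

__all__ = ["LatticeModel", "AreaFractionResult", "fit_lattice", "phi_angle",
           "area_fraction"]


@dataclass
class LatticeModel:
    """Fitted 2D unit cell of a PSII array."""

    a_A: float
    b_A: float
    alpha_deg: float  # folded into (0, 90]
    vec_a: np.ndarray  # 2D components, Angstrom
    vec_b: np.ndarray
    origin: np.ndarray
    rms_residual_A: float
    n_points_assigned: int
    n_points_total: int
    phi_deg: Optional[float] = None

    def __post_init__(self):
        if not (self.a_A >= self.b_A > 0):
            raise ValidationError("need a >= b > 0")
        if not (0 < self.alpha_deg <= 90):
            raise ValidationError("alpha must lie in (0, 90] degrees")
        if self.rms_residual_A < 0:
            raise ValidationError("rms residual must be non-negative")

    @property
    def alpha_supplement_deg(self) -> float:
        return 180.0 - self.alpha_deg

    @property
    def cell_area_A2(self) -> float:
        return self.a_A * self.b_A * np.sin(np.deg2rad(self.alpha_deg))

    def as_dict(self) -> dict:
        return {
            "a_A": self.a_A, "b_A": self.b_A,
            "alpha_deg": self.alpha_deg,
            "alpha_supplement_deg": self.alpha_supplement_deg,
            "phi_deg": self.phi_deg,
            "vec_a": list(map(float, self.vec_a)),
            "vec_b": list(map(float, self.vec_b)),
            "origin": list(map(float, self.origin)),
            "rms_residual_A": self.rms_residual_A,
            "n_points_assigned": self.n_points_assigned,
            "n_points_total": self.n_points_total,
        }

    def summary(self) -> str:
        phi = "-" if self.phi_deg is None else f"{self.phi_deg:.1f} deg"
        return (
            "PSII array unit cell\n"
            f"  a      {self.a_A:8.2f} A\n"
            f"  b      {self.b_A:8.2f} A\n"
            f"  alpha  {self.alpha_deg:8.2f} deg (or {self.alpha_supplement_deg:.2f})\n"
            f"  phi    {phi}\n"
            f"  rms    {self.rms_residual_A:.3f} A over "
            f"{self.n_points_assigned}/{self.n_points_total} points"
        )


@dataclass
class AreaFractionResult:
    """Crystalline-area fractions per micrograph, with a decile histogram."""

    per_micrograph: list
    histogram: np.ndarray  # counts per decile bin of [0, 1]
    bin_edges: np.ndarray

    def as_dict(self) -> dict:
        return {"per_micrograph": list(map(float, self.per_micrograph)),
                "histogram": list(map(int, self.histogram)),
                "bin_edges": list(map(float, self.bin_edges))}


# ---------------------------------------------------------------------------
# basis detection and refinement
# ---------------------------------------------------------------------------

def _fold_half_plane(v: np.ndarray) -> np.ndarray:
    """Map v and -v onto one representative (upper half-plane)."""
    v = v.copy()
    flip = (v[:, 1] < 0) | ((v[:, 1] == 0) & (v[:, 0] < 0))
    v[flip] *= -1
    return v


def _difference_modes(pts: np.ndarray, k: int, tol: float):
    """Greedy clustering of folded nearest-neighbour difference vectors.

    Returns cluster centres and support counts, sorted by vector length.
    """
    n = len(pts)
    kk = min(k + 1, n)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=kk)
    diffs = []
    for i in range(n):
        for j in idx[i, 1:]:
            diffs.append(pts[j] - pts[i])
    diffs = _fold_half_plane(np.asarray(diffs))
    order = np.argsort(np.linalg.norm(diffs, axis=1))
    centers: list[np.ndarray] = []
    sums: list[np.ndarray] = []
    counts: list[int] = []
    for v in diffs[order]:
        placed = False
        for ci in range(len(centers)):
            if np.linalg.norm(v - centers[ci]) < tol:
                sums[ci] += v
                counts[ci] += 1
                centers[ci] = sums[ci] / counts[ci]
                placed = True
                break
        if not placed:
            centers.append(v.copy())
            sums.append(v.copy())
            counts.append(1)
    order = np.argsort([np.linalg.norm(c) for c in centers])
    return [centers[i] for i in order], [counts[i] for i in order]


def _gauss_reduce(v1: np.ndarray, v2: np.ndarray):
    """Lagrange-Gauss reduction: the two shortest basis vectors of the lattice."""
    a, b = v1.astype(float), v2.astype(float)
    for _ in range(64):
        if np.linalg.norm(b) < np.linalg.norm(a):
            a, b = b, a
        m = round(float(np.dot(a, b) / np.dot(a, a)))
        r = b - m * a
        if np.linalg.norm(r) >= np.linalg.norm(b) - 1e-12:
            break
        b = r
    return a, b


def _refine(pts: np.ndarray, B: np.ndarray, origin: np.ndarray,
            n_iter: int = 4, drop_frac: float = 0.3):
    """Alternate integer index assignment and affine least squares.

    Points with residual above ``drop_frac x min(|a|, |b|)`` are excluded
    from the refinement (vacancies, edge points, junk).
    """
    assigned = np.ones(len(pts), dtype=bool)
    for _ in range(n_iter):
        idx = np.rint(np.linalg.solve(B, (pts - origin).T).T)
        # affine LS: pts ~ idx @ B.T + origin
        X = np.column_stack([idx, np.ones(len(pts))])
        sel = assigned
        if sel.sum() < 3:
            raise NoLatticeError("too few assignable points for refinement")
        sol, *_ = np.linalg.lstsq(X[sel], pts[sel], rcond=None)
        B = sol[:2].T
        if abs(np.linalg.det(B)) < 1e-9:
            raise NoLatticeError("degenerate (collinear) basis during refinement")
        origin = sol[2]
        res = np.linalg.norm(pts - (idx @ B.T + origin), axis=1)
        lim = drop_frac * min(np.linalg.norm(B[:, 0]), np.linalg.norm(B[:, 1]))
        assigned = res <= lim
    idx = np.rint(np.linalg.solve(B, (pts - origin).T).T)
    res = np.linalg.norm(pts - (idx @ B.T + origin), axis=1)
    lim = drop_frac * min(np.linalg.norm(B[:, 0]), np.linalg.norm(B[:, 1]))
    assigned = res <= lim
    return B, origin, assigned, res


def fit_lattice(
    points: PointSet2D,
    k_neighbors: int = 8,
    min_support_frac: float = 0.4,
    diagonal: Optional[Sequence[float]] = None,
) -> LatticeModel:
    """Estimate the 2D unit cell of a single crystalline domain.

    Raises :class:`NoLatticeError` when the difference-vector distribution
    has no two stable non-collinear modes (e.g. random points) or when the
    refined assignment covers too few points. Multi-domain input that still
    yields a basis is flagged with a high-residual warning.
    """
    pts = np.asarray(points.points, dtype=float)
    n = len(pts)
    if n < 6:
        raise DomainError(f"lattice fitting needs >= 6 points, got {n}")

    nn = cKDTree(pts).query(pts, k=2)[0][:, 1]
    d0 = float(np.median(nn))
    if d0 <= 0:
        raise NoLatticeError("coincident points")
    centers, counts = _difference_modes(pts, k_neighbors, tol=0.25 * d0)

    support = max(3, int(np.ceil(min_support_frac * n)))
    stable = [(c, m) for c, m in zip(centers, counts) if m >= support]
    if not stable:
        raise NoLatticeError(
            f"no stable difference-vector mode (max support "
            f"{max(counts) if counts else 0} < {support})"
        )
    v1 = stable[0][0]
    v2 = None
    for c, _ in stable[1:]:
        cross = v1[0] * c[1] - v1[1] * c[0]
        sin_angle = abs(cross) / (np.linalg.norm(v1) * np.linalg.norm(c))
        if sin_angle > np.sin(np.deg2rad(20.0)):
            v2 = c
            break
    if v2 is None:
        raise NoLatticeError("no second non-collinear stable mode; not a 2D lattice")

    B = np.column_stack([v1, v2])
    origin = pts[np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1))]
    B, origin, assigned, res = _refine(pts, B, origin)

    if assigned.sum() < max(6, 0.5 * n):
        raise NoLatticeError(
            f"only {int(assigned.sum())}/{n} points fit the candidate lattice"
        )

    va, vb = _gauss_reduce(B[:, 0], B[:, 1])
    # a is the longer reduced vector
    if np.linalg.norm(vb) > np.linalg.norm(va):
        va, vb = vb, va
    a_len = float(np.linalg.norm(va))
    b_len = float(np.linalg.norm(vb))
    cosang = float(np.dot(va, vb) / (a_len * b_len))
    alpha = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if alpha > 90.0:  # fold into (0, 90] by flipping b
        vb = -vb
        alpha = 180.0 - alpha

    rms = float(np.sqrt(np.mean(res[assigned] ** 2)))
    if rms > 0.15 * b_len:
        warnings.warn(
            f"high lattice residual ({rms:.1f} A vs b = {b_len:.1f} A); "
            "possible multi-domain input", stacklevel=2,
        )

    model = LatticeModel(
        a_A=a_len, b_A=b_len, alpha_deg=alpha,
        vec_a=va, vec_b=vb, origin=np.asarray(origin, dtype=float),
        rms_residual_A=rms,
        n_points_assigned=int(assigned.sum()), n_points_total=n,
    )

    diag = None
    if diagonal is not None:
        diag = np.asarray(diagonal, dtype=float)
    elif points.orientations is not None:
        diag = _mean_axial_direction(points.orientations)
    if diag is not None:
        model.phi_deg = phi_angle(model, diag)
    return model


def _mean_axial_direction(orientations: np.ndarray) -> np.ndarray:
    """Mean of axial (sign-free) unit vectors via alignment to the first."""
    ref = orientations[0]
    signs = np.where(orientations @ ref < 0, -1.0, 1.0)
    mean = (orientations * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        raise DomainError("orientation vectors cancel; no mean direction")
    return mean / norm


def phi_angle(model: LatticeModel, diagonal: Sequence[float]) -> float:
    """Unsigned angle in [0, 90] degrees between the a vector and the
    supercomplex diagonal direction."""
    d = np.asarray(diagonal, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise DomainError("zero diagonal vector")
    cosang = abs(float(np.dot(model.vec_a, d))) / (np.linalg.norm(model.vec_a) * nd)
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def area_fraction(
    masks: Sequence[BinaryMask],
    membranes: Optional[Sequence[BinaryMask]] = None,
) -> AreaFractionResult:
    """Crystalline-area fraction per micrograph and its decile histogram.

    ``fraction = crystalline pixels / membrane pixels``; without a companion
    membrane mask the whole raster counts as membrane. Micrographs whose
    membrane mask is empty are skipped with a warning.
    """
    if len(masks) == 0:
        raise DomainError("no masks supplied")
    if membranes is not None and len(membranes) != len(masks):
        raise ValidationError("one membrane mask per crystalline mask required")
    fractions = []
    for i, m in enumerate(masks):
        if membranes is not None:
            mem = membranes[i].data
            if mem.shape != m.data.shape:
                raise ValidationError(f"mask/membrane shape mismatch at index {i}")
            denom = int(np.count_nonzero(mem))
            if denom == 0:
                warnings.warn(f"micrograph {i}: empty membrane mask; skipped",
                              stacklevel=2)
                continue
            num = int(np.count_nonzero(m.data & mem))
        else:
            denom = m.data.size
            num = int(np.count_nonzero(m.data))
        fractions.append(num / denom)
    hist, edges = np.histogram(fractions, bins=10, range=(0.0, 1.0))
    return AreaFractionResult(per_micrograph=fractions, histogram=hist,
                              bin_edges=edges)
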