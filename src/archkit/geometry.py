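"""Module principal frames, inter-modular tilt/twist/skew, superposition and
ensemble statistics.

A module frame is an orthonormal right-handed triad: z along the long axis of
the (prolate) module, oriented N-to-C; x toward a chosen off-axis reference
atom; y = z cross x.  The orientation of one module relative to its
predecessor is decomposed as z-y-z Euler angles of the rotation taking frame i
into frame j, reported as tilt (deviation from collinear extension), twist
(net rotation about the long axes) and skew.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import BACKBONE_NAMES, Ensemble, ModuleSpan, Structure

__all__ = [
    "ModuleFrame",
    "JunctionAngles",
    "principal_frame",
    "frame_from_matrix",
    "inter_module_angles",
    "superpose",
    "ensemble_rmsd",
    "com_separation",
    "nsd",
]


@dataclass
class ModuleFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        M = self.matrix
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(M) < 0:
            raise ValueError("frame must be right-handed")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with columns (x, y, z)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


@dataclass
class JunctionAngles:
    """Inter-modular angles in degrees: tilt in [0, 180], twist and skew in
    (-180, 180].  tilt = 0 means collinear extension, where twist/skew are
    individually undefined (flagged; reported as 0 and the net axial rotation)."""

    tilt: float
    twist: float
    skew: float
    degenerate: bool = False


def _wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def principal_frame(structure: Structure, span: ModuleSpan,
                    mass_weighted: bool = False) -> ModuleFrame:
    """Orientation frame of one module from the inertia tensor of its heavy atoms.

    z is the eigenvector of the smallest inertia eigenvalue (long axis of a
    prolate body), sign-fixed so z . (CA(cys4) - CA(cys1)) > 0; x is the unit
    component of (ref_atom - centroid) orthogonal to z; y = z x x.  Unit masses
    by default.
    """
    idx = structure.select(residues=span.residues, heavy_only=True)
    if len(idx) < 3:
        raise ValueError(f"module {span.name}: too few heavy atoms in span")
    pts = structure.coords[idx]
    if mass_weighted:
        masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
        w = np.array([masses.get(structure.atoms[i].element.upper(), 12.0) for i in idx])
    else:
        w = np.ones(len(idx))
    origin = np.average(pts, axis=0, weights=w)
    d = pts - origin
    # inertia tensor: I = sum w (|r|^2 delta - r r^T)
    r2 = np.sum(d * d, axis=1)
    inertia = np.diag([np.sum(w * r2)] * 3) - (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(inertia)
    if evals[1] - evals[0] <= 0.01 * max(abs(evals[1]), 1e-30):
        raise ValueError(f"module {span.name}: long axis ill-defined "
                         "(two smallest inertia eigenvalues within 1%)")
    z = evecs[:, 0]
    nc = structure.atom(span.cys4, "CA").position - structure.atom(span.cys1, "CA").position
    if float(z @ nc) < 0:
        z = -z
    ref = structure.atom(*span.ref_atom).position
    v = ref - origin
    vn = np.linalg.norm(v)
    if vn == 0 or abs(float(v @ z) / vn) > np.cos(np.deg2rad(1.0)):
        raise ValueError(f"module {span.name}: reference atom within 1 degree of the long axis")
    x = v - (v @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return ModuleFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def frame_from_matrix(matrix: np.ndarray, origin: np.ndarray | None = None) -> ModuleFrame:
    M = np.asarray(matrix, dtype=float)
    return ModuleFrame(origin=np.zeros(3) if origin is None else np.asarray(origin, float),
                       x_axis=M[:, 0].copy(), y_axis=M[:, 1].copy(), z_axis=M[:, 2].copy())


def inter_module_angles(frame_i: ModuleFrame, frame_j: ModuleFrame,
                        eps: float = 1e-6) -> JunctionAngles:
    """Tilt/twist/skew between two module frames.

    With R the rotation carrying frame_i's triad into frame_j's, expressed in
    frame_i coordinates and decomposed as R = Rz(alpha) Ry(beta) Rz(gamma):
    tilt = beta, skew = alpha, twist = alpha + gamma.  At tilt -> 0 a pure
    rotation about the shared long axis is pure twist.
    """
    import warnings

    A = frame_i.matrix.T @ frame_j.matrix
    with warnings.catch_warnings():
        # at tilt 0/180 scipy warns about gimbal lock; handled explicitly below
        warnings.simplefilter("ignore", UserWarning)
        alpha, beta, gamma = Rotation.from_matrix(A).as_euler("ZYZ", degrees=True)
    tilt = float(beta)
    if tilt < eps or tilt > 180.0 - eps:
        # gimbal-degenerate: only alpha+gamma (tilt 0) / alpha-gamma (tilt 180)
        # is defined; scipy folds the whole rotation into gamma here.
        twist = _wrap_angle(float(alpha + gamma)) if tilt < eps else _wrap_angle(float(alpha - gamma))
        return JunctionAngles(tilt=tilt, twist=twist, skew=0.0, degenerate=True)
    return JunctionAngles(tilt=tilt,
                          twist=_wrap_angle(float(alpha + gamma)),
                          skew=_wrap_angle(float(alpha)))


def junction_rotation(tilt: float, twist: float, skew: float) -> np.ndarray:
    """Rotation matrix (frame_i coordinates) realizing given junction angles:
    inverse of :func:`inter_module_angles`."""
    return Rotation.from_euler("ZYZ", [skew, tilt, twist - skew], degrees=True).as_matrix()


def superpose(mobile: np.ndarray, target: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (proper rotation only, Kabsch).

    Returns (rotation, translation, rmsd) such that mobile @ rotation.T +
    translation best matches target.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (N, 3) coordinate sets required")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required")
    cm = np.average(mobile, axis=0, weights=weights)
    ct = np.average(target, axis=0, weights=weights)
    a = mobile - cm
    b = target - ct
    # collinearity guard
    if np.linalg.matrix_rank(a - a.mean(axis=0), tol=1e-8 * max(1.0, float(np.abs(a).max()))) < 2:
        raise ValueError("points are collinear; rotation under-determined")
    rot, rssd = Rotation.align_vectors(b, a, weights=weights)
    R = rot.as_matrix()
    t = ct - R @ cm
    resid = b - a @ R.T
    if weights is None:
        rmsd = float(np.sqrt(np.sum(resid ** 2) / n))
    else:
        w = np.asarray(weights, float)
        rmsd = float(np.sqrt(np.sum(w[:, None] * resid ** 2) / np.sum(w)))
    return R, t, rmsd


def _selection_indices(ref: Structure, selection) -> list[int]:
    if selection is None:
        return list(range(len(ref)))
    if isinstance(selection, str):
        if selection == "backbone":
            return ref.select(atom_names=BACKBONE_NAMES)
        if selection == "heavy":
            return ref.select(heavy_only=True)
        if selection == "all":
            return list(range(len(ref)))
        raise ValueError(f"unknown selection {selection!r}")
    if callable(selection):
        return ref.select(predicate=selection)
    return list(selection)


def ensemble_rmsd(ensemble: Ensemble, selection="backbone",
                  mode: str = "pairwise_mean") -> float:
    """Mean RMSD (Angstrom) over an ensemble after superposition on selection.

    'pairwise_mean': mean over all conformer pairs; 'to_mean': mean RMSD of
    each conformer to the coordinate-mean structure.  Backbone = N, CA, C, O.
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble_rmsd requires at least 2 conformers")
    idx = _selection_indices(ensemble.conformers[0], selection)
    if not idx:
        raise ValueError("empty atom selection")
    stacks = ensemble.coords[:, idx, :]
    n = len(stacks)
    if mode == "pairwise_mean":
        vals = [superpose(stacks[i], stacks[j])[2]
                for i in range(n) for j in range(i + 1, n)]
        return float(np.mean(vals))
    if mode == "to_mean":
        aligned = [stacks[0] - stacks[0].mean(axis=0)]
        for i in range(1, n):
            R, t, _ = superpose(stacks[i], aligned[0])
            aligned.append(stacks[i] @ R.T + t)
        for _ in range(3):  # iterate mean/alignment to a fixed point
            mean = np.mean(aligned, axis=0)
            aligned = []
            for i in range(n):
                R, t, _ = superpose(stacks[i], mean)
                aligned.append(stacks[i] @ R.T + t)
        mean = np.mean(aligned, axis=0)
        return float(np.mean([np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1)))
                              for c in aligned]))
    raise ValueError(f"unknown mode {mode!r}")


def com_separation(structure: Structure, span_i: ModuleSpan, span_j: ModuleSpan) -> float:
    """Distance (Angstrom) between unit-mass heavy-atom centroids of two spans."""
    ci = structure.coords[structure.select(residues=span_i.residues, heavy_only=True)]
    cj = structure.coords[structure.select(residues=span_j.residues, heavy_only=True)]
    if len(ci) == 0 or len(cj) == 0:
        raise ValueError("empty module span")
    return float(np.linalg.norm(ci.mean(axis=0) - cj.mean(axis=0)))


def _nsd_raw(a: np.ndarray, b: np.ndarray) -> float:
    ta, tb = cKDTree(a), cKDTree(b)
    # mean nearest-neighbour spacing within each set
    da = float(np.mean(ta.query(a, k=2)[0][:, 1]))
    db = float(np.mean(tb.query(b, k=2)[0][:, 1]))
    d_ab = tb.query(a)[0]  # each point of a to nearest of b
    d_ba = ta.query(b)[0]
    term_a = np.mean(d_ab ** 2) / db ** 2
    term_b = np.mean(d_ba ** 2) / da ** 2
    return float(np.sqrt(0.5 * (term_a + term_b)))


def nsd(points_a: np.ndarray, points_b: np.ndarray, align: bool = False) -> float:
    """Normalized spatial discrepancy between two point sets.

    Symmetrized mean squared nearest-neighbour distance, each directed term
    normalized by the other set's mean nearest-neighbour spacing, square-rooted.
    Values < 1 indicate good shape agreement.  With align=True the value is
    minimized over rigid transforms (coarse rotation grid + local refinement,
    both handednesses tried).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 3 or b.shape[1] != 3:
        raise ValueError("(N, 3) point sets required")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("point sets must contain at least 2 points")
    if not align:
        return _nsd_raw(a, b)

    from scipy.optimize import minimize

    bc = b - b.mean(axis=0)
    best = np.inf
    rng = np.random.default_rng(0)
    grid = list(Rotation.create_group("O"))  # 24 proper rotations of the cube
    grid += list(Rotation.random(200, random_state=rng))
    for mirror in (1.0, -1.0):
        am = (a - a.mean(axis=0)) * np.array([1.0, 1.0, mirror])

        def rot_cost(rv, am=am):
            R = Rotation.from_rotvec(rv).as_matrix()
            return _nsd_raw(am @ R.T, bc)

        def full_cost(x, am=am):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            return _nsd_raw(am @ R.T + x[3:], bc)

        cands = [(rot_cost(g.as_rotvec()), g.as_rotvec()) for g in grid]
        cands.sort(key=lambda t: t[0])
        # refine rotation alone from the best starts, then the full transform
        for _, rv in cands[:3]:
            r3 = minimize(rot_cost, rv, method="Nelder-Mead",
                          options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-9})
            r6 = minimize(full_cost, np.concatenate([r3.x, np.zeros(3)]),
                          method="Nelder-Mead",
                          options={"maxiter": 1200, "xatol": 1e-4, "fatol": 1e-9})
            best = min(best, float(r6.fun))
    return best
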