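"""Ensemble-optimization flexibility analysis.

A large pool of random conformers is generated from rigid bodies (modules,
plus any linkers internal to a rigid group) connected by flexible linkers
modeled as dummy-residue bead chains; a genetic algorithm then selects the
sub-ensemble (multiset) whose uniformly averaged scattering curve best fits
a target curve.  Comparing the size (Rg) distribution of the selected
ensemble with the pool distinguishes rigid from flexible architectures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import Architecture, ScatteringCurve, Structure
from .saxs import debye_curve, fit_curve

__all__ = ["RigiditySpec", "ConformerPool", "SelectionResult",
           "generate_pool", "select_ensemble", "rg_histogram"]

_A_TO_NM = 0.1


@dataclass
class RigiditySpec:
    """Which parts move as one body.

    rigid_groups: lists of consecutive module names; the linkers between
    modules of the same group are carried along rigidly.  Linkers between
    consecutive groups are the flexible ones.
    """

    rigid_groups: list[list[str]]

    def validate(self, arch: Architecture) -> list[int]:
        """Check coverage/ordering; return the flexible linker indices."""
        seen: list[str] = []
        for g in self.rigid_groups:
            if not g:
                raise ValueError("empty rigid group")
            idxs = [arch.module_index(n) for n in g]
            if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
                raise ValueError(f"rigid group {g} is not a consecutive run of modules")
            seen.extend(g)
        if sorted(seen) != sorted(m.name for m in arch.modules):
            raise ValueError("rigid groups must cover every module exactly once")
        order = [arch.module_index(g[0]) for g in self.rigid_groups]
        if order != sorted(order):
            raise ValueError("rigid groups must be listed N-to-C")
        flexible = []
        boundary = -1
        for g in self.rigid_groups:
            first = arch.module_index(g[0])
            if boundary >= 0:
                flexible.append(first - 1)  # linker index preceding this group
            boundary = arch.module_index(g[-1])
        return flexible


@dataclass
class ConformerPool:
    conformers: list[np.ndarray]        # CA-bead coordinates, Angstrom
    rg: np.ndarray                      # nm, per conformer
    curves: np.ndarray                  # (n_conformers, n_s) model intensities
    s_grid: np.ndarray                  # nm^-1
    seed: int
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class SelectionResult:
    indices: list[int]                  # chosen multiset of pool indices
    chi: float
    history: list[float]                # best chi per generation
    rg_selected: np.ndarray             # nm

    @property
    def multiplicities(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i in self.indices:
            out[i] = out.get(i, 0) + 1
        return out


def _group_beads(source: Structure, arch: Architecture,
                 groups: list[list[str]]) -> list[np.ndarray]:
    """CA coordinates of each rigid group (modules + internal linkers)."""
    out = []
    for g in groups:
        lo = arch.module(g[0]).cys1
        hi = arch.module(g[-1]).cys4
        idx = source.select(residues=range(lo, hi + 1), atom_names=("CA",))
        if not idx:
            raise ValueError(f"no CA atoms for rigid group {g}")
        out.append(source.coords[idx])
    return out


def _sample_chain(rng: np.random.Generator, start: np.ndarray, prev: np.ndarray,
                  n: int, bond: float = 3.8) -> np.ndarray:
    """Dummy-residue chain: bond 3.8 A, bond angle uniform in [90, 180] deg,
    dihedral uniform; ``prev`` sets the incoming direction."""
    pts = [start]
    d1 = start - prev
    d1 /= np.linalg.norm(d1)
    for _ in range(n):
        theta = np.deg2rad(rng.uniform(90.0, 180.0))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        # orthonormal frame around the incoming direction
        a = np.array([1.0, 0.0, 0.0])
        if abs(d1 @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d1, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d1, e1)
        step = (np.cos(np.pi - theta) * d1
                + np.sin(np.pi - theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
        new = pts[-1] + bond * step
        d1 = step
        pts.append(new)
    return np.array(pts[1:])


def generate_pool(arch: Architecture, rigidity: RigiditySpec, source: Structure,
                  n: int = 10000, seed: int = 0,
                  s_grid: np.ndarray | None = None,
                  clash_cutoff: float = 4.0, max_attempts: int = 100) -> ConformerPool:
    """Random conformer pool with rigid bodies and flexible dummy-bead linkers.

    Each conformer: rigid-group CA beads from ``source``, flexible linkers
    resampled as random chains, the following group re-attached at the linker
    end with a uniformly random orientation.  Conformers with inter-body bead
    clashes (< ``clash_cutoff`` Angstrom between non-adjacent bodies) are
    rejected and resampled (cap ``max_attempts`` per conformer).
    """
    flexible = rigidity.validate(arch)
    groups = _group_beads(source, arch, rigidity.rigid_groups)
    linker_n = []
    for li in flexible:
        lk = arch.linkers[li]
        if len(lk) < 1:
            raise ValueError(f"flexible linker {li} has no residues")
        linker_n.append(len(lk))
    if s_grid is None:
        s_grid = np.linspace(0.05, 3.0, 60)
    rng = np.random.default_rng(seed)
    conformers: list[np.ndarray] = []
    n_rejected = 0
    while len(conformers) < n:
        for attempt in range(max_attempts):
            bodies = [groups[0]]
            ok = True
            for gi in range(1, len(groups)):
                nres = linker_n[gi - 1]
                prev_body = bodies[-1]
                start = prev_body[-1]
                prev = prev_body[-2] if len(prev_body) > 1 else start - rng.normal(size=3)
                chain = _sample_chain(rng, start, prev, nres + 1)
                link, anchor = chain[:-1], chain[-1]
                g = groups[gi]
                R = Rotation.random(random_state=rng).as_matrix()
                moved = (g - g[0]) @ R.T + anchor
                bodies.append(link)
                bodies.append(moved)
            # clash screen between non-adjacent bodies
            for i in range(len(bodies)):
                for j in range(i + 2, len(bodies)):
                    if cKDTree(bodies[i]).query(bodies[j])[0].min() < clash_cutoff:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                conformers.append(np.vstack(bodies))
                break
            n_rejected += 1
        else:
            raise ValueError("clash-rejection cap exceeded: geometry overconstrained")
    rgs = np.empty(len(conformers))
    curves = np.empty((len(conformers), len(s_grid)))
    for i, pts in enumerate(conformers):
        d = pts - pts.mean(axis=0)
        rgs[i] = np.sqrt(np.mean(np.sum(d * d, axis=1))) * _A_TO_NM
        curves[i] = debye_curve(pts, s_grid).I
    return ConformerPool(conformers=conformers, rg=rgs, curves=curves,
                         s_grid=np.asarray(s_grid, float), seed=seed,
                         n_rejected=n_rejected)


def _chi_of(avg: np.ndarray, target: ScatteringCurve) -> float:
    model = ScatteringCurve(target.s, avg)
    return fit_curve(target, model).chi


def select_ensemble(pool: ConformerPool, target: ScatteringCurve,
                    ensemble_size: int = 20, population: int = 50,
                    generations: int = 100, mutation: float = 0.1,
                    crossover: float = 0.5, elitism: int = 1,
                    seed: int = 0) -> SelectionResult:
    """Genetic-algorithm selection of the conformer multiset whose averaged
    curve best fits the target (elitist GA: best chi never increases)."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    if not (len(pool.s_grid) == len(target.s) and np.allclose(pool.s_grid, target.s)):
        from scipy.interpolate import CubicSpline
        curves = CubicSpline(pool.s_grid, pool.curves, axis=1)(target.s)
    else:
        curves = pool.curves
    npool = len(pool)
    rng = np.random.default_rng(seed)
    if npool == 1:
        idx = [0] * ensemble_size
        chi = _chi_of(curves[0], target)
        return SelectionResult(idx, chi, [chi], pool.rg[[0]])

    pop = rng.integers(0, npool, size=(population, ensemble_size))

    def fitness(chrom: np.ndarray) -> float:
        return _chi_of(curves[chrom].mean(axis=0), target)

    scores = np.array([fitness(c) for c in pop])
    history: list[float] = []
    for _ in range(generations):
        order = np.argsort(scores, kind="stable")
        pop, scores = pop[order], scores[order]
        history.append(float(scores[0]))
        new = [pop[i].copy() for i in range(elitism)]
        while len(new) < population:
            # tournament parent selection (k = 3)
            cand = rng.integers(0, population, size=3)
            p1 = pop[cand[np.argmin(scores[cand])]]
            cand = rng.integers(0, population, size=3)
            p2 = pop[cand[np.argmin(scores[cand])]]
            if rng.random() < crossover:
                mask = rng.random(ensemble_size) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mut = rng.random(ensemble_size) < mutation
            for k in np.flatnonzero(mut):
                if rng.random() < 0.5:
                    # duplication move: repeat another selected conformer,
                    # letting multiplicity (= ensemble weight) build up
                    child[k] = child[rng.integers(0, ensemble_size)]
                else:
                    child[k] = rng.integers(0, npool)
            new.append(child)
        pop = np.array(new)
        scores = np.array([fitness(c) for c in pop])
    order = np.argsort(scores, kind="stable")
    best = pop[order[0]].copy()
    chi = float(scores[order[0]])

    # pure single-conformer ensembles are cheap to scan exhaustively and are
    # the exact optimum whenever the target comes from one rigid conformer
    w = 1.0 / target.sigma ** 2
    cnum1 = (curves * (w * target.I)[None, :]).sum(axis=1)
    cden1 = (curves ** 2 * w[None, :]).sum(axis=1)
    c1 = cnum1 / np.maximum(cden1, 1e-300)
    resid1 = (target.I[None, :] - c1[:, None] * curves) / target.sigma[None, :]
    chi1 = np.sqrt((resid1 ** 2).sum(axis=1) / max(len(target.I) - 1, 1))
    j1 = int(np.argmin(chi1))
    if chi1[j1] < chi:
        best = np.full(ensemble_size, j1)
        chi = float(chi1[j1])

    # greedy single-slot refinement of the GA winner (vectorized over the
    # pool); keeps the best-chi trajectory monotone
    for _ in range(20):
        improved = False
        for k in range(ensemble_size):
            rest = curves[best].sum(axis=0) - curves[best[k]]
            cand = (rest[None, :] + curves) / ensemble_size
            cnum = (cand * (w * target.I)[None, :]).sum(axis=1)
            cden = (cand ** 2 * w[None, :]).sum(axis=1)
            c = cnum / np.maximum(cden, 1e-300)
            resid = (target.I[None, :] - c[:, None] * cand) / target.sigma[None, :]
            chis = np.sqrt((resid ** 2).sum(axis=1) / max(len(target.I) - 1, 1))
            j = int(np.argmin(chis))
            if chis[j] < chi - 1e-12:
                best[k] = j
                chi = float(chis[j])
                improved = True
        if not improved:
            break
    history.append(chi)
    return SelectionResult(sorted(int(i) for i in best), chi, history,
                           pool.rg[best])


def rg_histogram(values, bins: int = 30) -> dict:
    """Normalized Rg histogram with a two-means bimodality flag.

    The best two-class split (1-d k-means / Otsu style) proposes two
    sub-populations; the flag is raised when each holds >= 10% of the values,
    their means are separated by more than twice the pooled within-class
    spread, AND the (smoothed) density at the valley between the class means
    drops below half the smaller of the two class peaks — the last condition
    keeps broad unimodal distributions from being flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    hist, edges = np.histogram(values, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bimodal = False
    mode = float(centers[np.argmax(hist)])
    if values.size >= 10 and np.ptp(values) > 0:
        v = np.sort(values)
        best = (np.inf, None)
        for cut in range(2, len(v) - 2):
            a, b = v[:cut], v[cut:]
            w = len(a) * np.var(a) + len(b) * np.var(b)
            if w < best[0]:
                best = (w, cut)
        cut = best[1]
        a, b = v[:cut], v[cut:]
        wa, wb = len(a) / len(v), len(b) / len(v)
        spread = np.sqrt((len(a) * np.var(a) + len(b) * np.var(b)) / len(v))
        gap_ok = (min(wa, wb) >= 0.10
                  and (b.mean() - a.mean()) > 2.0 * max(spread, 1e-12))
        if gap_ok:
            smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
            in_a = centers <= a.mean()
            in_b = centers >= b.mean()
            between = (centers > a.mean()) & (centers < b.mean())
            if in_a.any() and in_b.any() and between.any():
                peak_a = smooth[in_a].max()
                peak_b = smooth[in_b].max()
                valley = smooth[between].min()
                bimodal = bool(valley < 0.5 * min(peak_a, peak_b))
    return {"centers": centers, "density": hist, "mode": mode,
            "width": float(np.std(values)), "bimodal": bimodal}
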