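"""Hybrid restrained annealing: rigid modules and flexible linkers driven by
NOE upper bounds and/or a target scattering curve, with optional
ensemble-averaged (N = 2) restraint evaluation; plus NOE-violation reporting.

The conformational search is Metropolis Monte Carlo over pivot rotations at
flexible-linker atoms (every atom downstream of a random linker pivot is
rotated rigidly), cooled through a two-stage temperature schedule with the
experimental terms introduced by a multiplicative ramp during the first
stage.  With no restraint list this reduces to SAXS-only rigid-body fitting;
with no curve it is NOE-only annealing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .core import Architecture, Ensemble, RestraintList, ScatteringCurve, Structure
from .flexibility import RigiditySpec

__all__ = ["AnnealSchedule", "HybridEnergy", "ViolationReport",
           "noe_violations", "anneal", "AnnealResult"]

_A_TO_NM = 0.1


@dataclass
class AnnealSchedule:
    """Two-stage cooling: stage 1 from 2000 K to 600 K in 50-K intervals with
    the experimental weights ramped up multiplicatively, stage 2 from 600 K
    to 100 K in 25-K intervals at full weight; ``moves_per_temp`` Monte-Carlo
    moves at each temperature."""

    stage1_start: float = 2000.0
    stage1_stop: float = 600.0
    stage1_step: float = 50.0
    stage2_stop: float = 100.0
    stage2_step: float = 25.0
    moves_per_temp: int = 300

    def temperatures(self) -> tuple[np.ndarray, np.ndarray]:
        t1 = np.arange(self.stage1_start, self.stage1_stop - 1e-9, -self.stage1_step)
        if t1[-1] != self.stage1_stop:
            t1 = np.append(t1, self.stage1_stop)
        t2 = np.arange(self.stage1_stop - self.stage2_step,
                       self.stage2_stop - 1e-9, -self.stage2_step)
        if t2[-1] != self.stage2_stop:
            t2 = np.append(t2, self.stage2_stop)
        if np.any(np.diff(np.concatenate([t1, t2])) >= 0):
            raise ValueError("temperatures must be strictly decreasing")
        if self.moves_per_temp <= 0:
            raise ValueError("moves_per_temp must be positive")
        return t1, t2


@dataclass
class HybridEnergy:
    e_noe: float
    e_saxs: float
    e_clash: float
    w_noe: float
    w_saxs: float

    @property
    def total(self) -> float:
        return self.w_noe * self.e_noe + self.w_saxs * self.e_saxs + self.e_clash


@dataclass
class ViolationReport:
    distances: np.ndarray
    violations: np.ndarray
    threshold: float
    unresolved: list[tuple]

    @property
    def n_above(self) -> int:
        return int(np.sum(self.violations > self.threshold))

    @property
    def max_violation(self) -> float:
        return float(self.violations.max()) if self.violations.size else 0.0

    @property
    def mean_violation(self) -> float:
        return float(self.violations.mean()) if self.violations.size else 0.0


def noe_violations(obj: Structure | Ensemble, rlist: RestraintList,
                   threshold: float = 0.5, averaging: str = "single") -> ViolationReport:
    """Per-restraint distances and upper-bound violations.

    averaging 'single' uses the (first) structure; 'r6_ensemble' uses the
    NOE-appropriate ensemble average d_eff = (mean over members of d^-6)^(-1/6).
    """
    members = obj.conformers if isinstance(obj, Ensemble) else [obj]
    if averaging == "single":
        members = members[:1]
    elif averaging != "r6_ensemble":
        raise ValueError(f"unknown averaging {averaging!r}")
    ref = members[0]
    dists, viols, unresolved = [], [], []
    for r in rlist:
        if not (ref.has_atom(*r.atom_a) and ref.has_atom(*r.atom_b)):
            unresolved.append((r.atom_a, r.atom_b))
            continue
        ds = np.array([np.linalg.norm(m.atom(*r.atom_a).position
                                      - m.atom(*r.atom_b).position)
                       for m in members])
        d = float(np.mean(ds ** -6.0) ** (-1.0 / 6.0))
        dists.append(d)
        viols.append(max(0.0, d - r.upper_bound))
    return ViolationReport(np.array(dists), np.array(viols), threshold, unresolved)


@dataclass
class AnnealResult:
    ensemble: Ensemble
    trace: list[dict] = field(default_factory=list)
    best_energy: HybridEnergy | None = None
    start_energy: HybridEnergy | None = None


class _EnergyModel:
    """Vectorized hybrid energy on coordinate arrays of one or two members."""

    def __init__(self, start: Structure, arch: Architecture,
                 restraints: RestraintList | None,
                 target: ScatteringCurve | None,
                 w_noe: float, clash_cutoff: float = 4.0,
                 k_bond: float = 10.0):
        self.clash_cutoff = clash_cutoff
        # chain-connectivity term: consecutive-atom distances are restrained
        # to their starting values (rigid-segment moves preserve them exactly;
        # whole-group rotations/translations stretch the two boundary bonds
        # and are pulled back harmonically)
        self.k_bond = k_bond
        self.bond_ref = np.linalg.norm(np.diff(start.coords, axis=0), axis=1)
        self.ca_idx = np.array(start.select(atom_names=("CA",)), dtype=int)
        if target is not None and len(self.ca_idx) < 2:
            raise ValueError("need CA beads for the scattering term")
        # module membership of CA beads (for the soft-sphere clash screen);
        # the two junction-flanking residues of each module are exempt
        self.mod_ca: list[np.ndarray] = []
        for m in arch.modules:
            skip = {m.cys1, m.cys1 + 1, m.cys4, m.cys4 - 1}
            rows = [k for k, i in enumerate(self.ca_idx)
                    if start.atoms[i].residue_number in m.residues
                    and start.atoms[i].residue_number not in skip]
            self.mod_ca.append(np.array(rows, dtype=int))
        self.ia = self.ib = self.ub = None
        if restraints is not None and len(restraints):
            ia, ib, ub = [], [], []
            for r in restraints:
                if start.has_atom(*r.atom_a) and start.has_atom(*r.atom_b):
                    ia.append(start._index[r.atom_a])
                    ib.append(start._index[r.atom_b])
                    ub.append(r.upper_bound)
            self.ia = np.array(ia, int)
            self.ib = np.array(ib, int)
            self.ub = np.array(ub, float)
        self.target = target
        self.w_noe = w_noe
        if target is not None:
            # binned-distance Debye acceleration: pair distances are counted
            # into 0.01-nm bins and multiplied into a precomputed sinc matrix
            self._bin = 0.01
            span = np.ptp(start.coords, axis=0)
            dmax_nm = 3.0 * float(np.linalg.norm(span)) * _A_TO_NM + 1.0
            self._nbins = int(np.ceil(dmax_nm / self._bin)) + 2
            centers = (np.arange(self._nbins) + 0.5) * self._bin
            self._sinc = np.sinc(np.outer(np.asarray(target.s, float), centers) / np.pi)

    def member_curve(self, coords: np.ndarray) -> np.ndarray:
        pts = coords[self.ca_idx] * _A_TO_NM
        d = pdist(pts)
        h = np.bincount((d / self._bin).astype(np.intp),
                        minlength=self._nbins)[:self._nbins]
        return len(pts) + 2.0 * (self._sinc @ h)

    def e_noe(self, members: list[np.ndarray]) -> float:
        if self.ia is None or len(self.ia) == 0:
            return 0.0
        d6 = np.zeros(len(self.ia))
        for c in members:
            d = np.linalg.norm(c[self.ia] - c[self.ib], axis=1)
            d6 += d ** -6.0
        deff = (d6 / len(members)) ** (-1.0 / 6.0)
        v = np.maximum(0.0, deff - self.ub)
        return float(np.sum(v * v))

    def chi2(self, curves: list[np.ndarray]) -> float:
        if self.target is None:
            return 0.0
        Im = np.mean(curves, axis=0)
        t = self.target
        w = 1.0 / t.sigma ** 2
        c = float(np.sum(w * t.I * Im) / np.sum(w * Im * Im))
        return float(np.sum(((t.I - c * Im) / t.sigma) ** 2) / max(len(t.I) - 1, 1))

    def e_bond(self, members: list[np.ndarray]) -> float:
        total = 0.0
        for c in members:
            d = np.linalg.norm(np.diff(c, axis=0), axis=1)
            total += float(np.sum((d - self.bond_ref) ** 2))
        return self.k_bond * total

    def e_clash(self, members: list[np.ndarray]) -> float:
        cut = self.clash_cutoff
        total = 0.0
        for c in members:
            ca = c[self.ca_idx]
            for i in range(len(self.mod_ca)):
                for j in range(i + 1, len(self.mod_ca)):
                    d = cdist(ca[self.mod_ca[i]], ca[self.mod_ca[j]])
                    close = d[d < cut]
                    if close.size:
                        total += float(np.sum((cut - close) ** 2))
        return total


def anneal(start: Structure, arch: Architecture, rigidity: RigiditySpec,
           restraints: RestraintList | None = None,
           target_curve: ScatteringCurve | None = None,
           schedule: AnnealSchedule | None = None,
           ensemble_n: int = 1, seed: int = 0,
           w_noe: float = 1.0, w_saxs: float | None = None,
           max_step_deg: float = 30.0, min_step_deg: float = 1.5) -> AnnealResult:
    """Metropolis Monte-Carlo annealing of flexible junctions against NOE
    and/or SAXS restraints, optionally as an ensemble of N members with
    ensemble-averaged restraint energies.

    Moves are pivot rotations about randomly chosen flexible-linker atoms
    (everything downstream rotates rigidly), with the step size cooled along
    the temperature schedule.  Same seed, same inputs -> identical output.
    Returns the best-so-far ensemble and a per-temperature energy trace.
    """
    if restraints is None and target_curve is None:
        raise ValueError("need at least one restraint source")
    schedule = schedule or AnnealSchedule()
    flexible = rigidity.validate(arch)
    if not flexible:
        model = _EnergyModel(start, arch, restraints, target_curve, w_noe)
        members = [start.coords] * ensemble_n
        curves = ([model.member_curve(c) for c in members]
                  if target_curve is not None else [])
        chi2 = model.chi2(curves) if curves else 0.0
        e = HybridEnergy(model.e_noe(members), chi2,
                         model.e_clash(members) + model.e_bond(members),
                         w_noe, w_saxs if w_saxs is not None else 1.0)
        return AnnealResult(Ensemble([start] * ensemble_n), [], e, e)

    rng = np.random.default_rng(seed)
    model = _EnergyModel(start, arch, restraints, target_curve, w_noe)

    # pivot atoms: atoms of flexible linker residues (in chain order)
    pivots_by_linker: list[np.ndarray] = []
    for li in flexible:
        lk = arch.linkers[li]
        idx = start.select(residues=lk)
        if not idx:
            raise ValueError(f"flexible linker {li} has no atoms in the structure")
        pivots_by_linker.append(np.array(idx, int))

    # rigid-group atom blocks (modules plus any linkers internal to a group)
    group_atoms: list[np.ndarray] = []
    for g in rigidity.rigid_groups:
        lo = arch.module(g[0]).cys1
        hi = arch.module(g[-1]).cys4
        group_atoms.append(np.array(start.select(residues=range(lo, hi + 1)), int))

    members = [start.coords.copy() for _ in range(ensemble_n)]
    curves = ([model.member_curve(c) for c in members]
              if target_curve is not None else [None] * ensemble_n)

    def energy() -> HybridEnergy:
        chi2 = model.chi2(curves) if target_curve is not None else 0.0
        return HybridEnergy(model.e_noe(members), chi2,
                            model.e_clash(members) + model.e_bond(members),
                            w_noe, w_s)

    # auto-balance: make the SAXS term comparable to the NOE term at start
    w_s = 1.0
    e0 = energy()
    if w_saxs is not None:
        w_s = w_saxs
    elif target_curve is not None and e0.e_saxs > 0:
        w_s = max(e0.e_noe, 1.0) / e0.e_saxs
    e0 = energy()

    t1, t2 = schedule.temperatures()
    temps = np.concatenate([t1, t2])
    n_ramp = len(t1)
    t_max = temps[0]
    e_ref = max(e0.total, 1e-3)
    tscale = e_ref / (10.0 * t_max)  # kT at the hottest stage ~ E_start / 10

    best_members = [c.copy() for c in members]
    best_e = e0
    cur_total = None
    trace: list[dict] = []

    for ti, T in enumerate(temps):
        ramp = min(1.0, (ti + 1) / n_ramp)
        kT = tscale * T
        step = min_step_deg + (max_step_deg - min_step_deg) * (T / t_max)

        def ramped_total(e: HybridEnergy) -> float:
            return ramp * (e.w_noe * e.e_noe + e.w_saxs * e.e_saxs) + e.e_clash

        e_cur = energy()
        cur_total = ramped_total(e_cur)
        for _ in range(schedule.moves_per_temp):
            m = int(rng.integers(0, ensemble_n))
            old = members[m]
            new = old.copy()
            kind = rng.random()
            if kind < 0.65:
                # pivot move in a flexible linker: everything downstream
                # rotates; 'torsion' flavour uses the bond into the pivot as
                # the axis, preserving all local (1-2, 1-3) chain geometry
                li = int(rng.integers(0, len(pivots_by_linker)))
                piv = int(rng.choice(pivots_by_linker[li]))
                if kind < 0.50 and piv > 0:
                    axis = old[piv] - old[piv - 1]
                    axis = axis / max(np.linalg.norm(axis), 1e-9)
                else:
                    axis = rng.normal(size=3)
                    axis /= np.linalg.norm(axis)
                ang = np.deg2rad(rng.normal(0.0, step))
                R = Rotation.from_rotvec(ang * axis).as_matrix()
                center = old[piv]
                new[piv + 1:] = (old[piv + 1:] - center) @ R.T + center
            elif kind < 0.90:
                # spin a rigid group about its own end-to-end axis through
                # its centroid: the scattering curve is nearly blind to this
                # rotation, but NOEs are not — it explores the orientation
                # degeneracy at almost constant shape
                gi = int(rng.integers(0, len(group_atoms)))
                idx = group_atoms[gi]
                axis = old[idx[-1]] - old[idx[0]]
                axis = axis / max(np.linalg.norm(axis), 1e-9)
                ang = np.deg2rad(rng.normal(0.0, 1.5 * step))
                R = Rotation.from_rotvec(ang * axis).as_matrix()
                center = old[idx].mean(axis=0)
                new[idx] = (old[idx] - center) @ R.T + center
            else:
                # small rigid translation of one group
                gi = int(rng.integers(0, len(group_atoms)))
                idx = group_atoms[gi]
                new[idx] = old[idx] + rng.normal(0.0, 0.02 * step, size=3)
            members[m] = new
            old_curve = curves[m]
            if target_curve is not None:
                curves[m] = model.member_curve(new)
            e_new = energy()
            new_total = ramped_total(e_new)
            dE = new_total - cur_total
            if dE <= 0 or rng.random() < np.exp(-dE / max(kT, 1e-12)):
                cur_total = new_total
                if e_new.total < best_e.total:
                    best_e = e_new
                    best_members = [c.copy() for c in members]
            else:
                members[m] = old
                curves[m] = old_curve
        trace.append({"T": float(T), "ramp": ramp, "best_total": best_e.total,
                      "e_noe": best_e.e_noe, "e_saxs": best_e.e_saxs,
                      "e_clash": best_e.e_clash})

    final = Ensemble([start.with_coords(c) for c in best_members],
                     label=f"{start.label}-annealed")
    return AnnealResult(final, trace, best_e, e0)
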