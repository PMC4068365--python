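"""Synthetic inputs for every pipeline stage: pseudo-module structures,
multi-module chains with prescribed junction angles, noisy scattering
curves, contact-derived NOE lists and jittered ensembles.

The dummy modules emulate ~4-nm prolate beta-sandwich modules (51-62
residues, boundary cysteines, 3-8-residue linkers) with a backbone-only
(N, CA, C, O) helical winding; no side chains or chemistry.  All generators
are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import (Architecture, Atom, Ensemble, ModuleSpan, Restraint,
                   RestraintList, ScatteringCurve, Structure)
from .geometry import junction_rotation, principal_frame

__all__ = ["make_module", "build_chain", "simulate_curve", "synth_noe",
           "jitter_ensemble"]

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _residue_atoms(serial0: int, resnum: int, resname: str, ca: np.ndarray,
                   axis: np.ndarray, side: np.ndarray) -> list[Atom]:
    """Backbone quartet around a CA position; axis/side are unit vectors."""
    up = np.cross(axis, side)
    offsets = {
        "N": -1.2 * axis + 0.4 * side,
        "CA": np.zeros(3),
        "C": 1.2 * axis + 0.4 * side,
        "O": 1.4 * axis + 1.1 * up,
    }
    out = []
    for i, name in enumerate(("N", "CA", "C", "O")):
        out.append(Atom(serial0 + i, name, resnum, resname, _ELEMENT[name],
                        ca + offsets[name]))
    return out


def make_module(n_residues: int = 60, length: float = 38.0, radius: float = 8.0,
                seed: int = 0, name: str = "CCP") -> tuple[Structure, ModuleSpan]:
    """A prolate pseudo-module: backbone quartets wound helically along a
    spheroidal envelope of the given half-lengths, long axis = +z.

    First and last residues are named CYS (span boundaries); the reference
    atom is the CA of a mid-module residue, off-axis by construction.
    """
    if n_residues < 8:
        raise ValueError("n_residues must be >= 8")
    if length <= 0 or radius <= 0 or radius >= length:
        raise ValueError("module must be prolate: 0 < radius < length")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    atoms: list[Atom] = []
    zhat = np.array([0.0, 0.0, 1.0])
    for i in range(n_residues):
        frac = i / (n_residues - 1)
        z = (-0.5 + frac) * (length - 4.0)
        rho = radius * np.sqrt(max(0.05, 1.0 - (2.0 * frac - 1.0) ** 2))
        theta = phase + i * np.deg2rad(100.0)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = rho * u + z * zhat
        resname = "CYS" if i in (0, n_residues - 1) else ("ALA" if i % 2 else "GLY")
        atoms.extend(_residue_atoms(4 * i + 1, i + 1, resname, ca, zhat, u))
    struct = Structure(atoms, label=name)
    span = ModuleSpan(name=name, cys1=1, cys4=n_residues,
                      ref_atom=(n_residues // 2, "CA"))
    return struct, span


def _linker_ca_path(start: np.ndarray, end: np.ndarray, n_res: int,
                    offset_dir: np.ndarray, spacing: float = 3.8) -> np.ndarray:
    """CA positions of a bowed linker bridge: a half-sine arc whose amplitude
    is solved so consecutive beads sit ~``spacing`` Angstrom apart even when
    the chord is shorter than the contour length (modules can then approach
    each other across a compact junction, as real tilted module pairs do)."""
    seg = end - start
    chord = np.linalg.norm(seg)
    seg_hat = seg / chord
    side = offset_dir - (offset_dir @ seg_hat) * seg_hat
    nrm = np.linalg.norm(side)
    if nrm < 1e-9:
        side = np.zeros(3)
        side[np.argmin(np.abs(seg_hat))] = 1.0
        side -= (side @ seg_hat) * seg_hat
        nrm = np.linalg.norm(side)
    side /= nrm
    f = np.arange(1, n_res + 2) / (n_res + 1)
    f_all = np.concatenate([[0.0], f])

    def path(h: float) -> np.ndarray:
        return (start[None, :] + f_all[:, None] * seg[None, :]
                + h * np.sin(np.pi * f_all)[:, None] * side[None, :])

    target = spacing * (n_res + 1)
    if chord >= target:
        h_best = 0.0
    else:
        lo, hi = 0.0, 2.0 * target
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            L = float(np.sum(np.linalg.norm(np.diff(path(mid), axis=0), axis=1)))
            if L < target:
                lo = mid
            else:
                hi = mid
        h_best = 0.5 * (lo + hi)
    return path(h_best)[1:-1], seg_hat, side


def _linker_atoms(serial0: int, res0: int, start: np.ndarray, end: np.ndarray,
                  n_res: int, offset_dir: np.ndarray) -> list[Atom]:
    cas, seg_hat, side = _linker_ca_path(start, end, n_res, offset_dir)
    atoms = []
    for l, ca in enumerate(cas, start=1):
        atoms.extend(_residue_atoms(serial0 + 4 * (l - 1), res0 + l - 1, "GLY",
                                    ca, seg_hat, side))
    return atoms


def build_chain(modules: list[tuple[Structure, ModuleSpan]],
                junctions: list[tuple[float, float, float, int]],
                seed: int = 0, clash_cutoff: float = 4.0,
                max_tries: int = 100) -> tuple[Structure, Architecture]:
    """Assemble modules into a chain realizing prescribed junction angles.

    ``junctions[k] = (tilt, twist, skew, linker_n_residues)`` places module
    k+1 so that the tilt/twist/skew between recomputed principal frames
    equals the request (to numerical precision); the linker is a bridge of
    dummy glycines.  Residues are renumbered consecutively.
    """
    if len(junctions) != len(modules) - 1:
        raise ValueError("need exactly one junction per consecutive module pair")
    rng = np.random.default_rng(seed)

    placed: list[Structure] = [modules[0][0]]
    spans: list[ModuleSpan] = [modules[0][1]]
    frames = [principal_frame(placed[0], spans[0])]
    linker_atom_blocks: list[list[Atom]] = []

    for k, (tilt, twist, skew, linker_n) in enumerate(junctions):
        if not 0.0 <= tilt <= 180.0:
            raise ValueError("tilt must lie in [0, 180] degrees")
        if linker_n < 1:
            raise ValueError("linker must contain at least 1 residue")
        F = frames[k]
        M_new = F.matrix @ junction_rotation(tilt, twist, skew)
        mod, span = modules[k + 1]
        f0 = principal_frame(mod, span)
        R = M_new @ f0.matrix.T
        z_prev = F.z_axis
        z_new = M_new[:, 2]
        u = z_prev + z_new
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-6 else z_new
        a = placed[k].atom(spans[k].cys4, "CA").position

        # base junction gap well below the linker contour (the bridge bows),
        # so compact tilts bring module surfaces into NOE range; escalated if
        # the prescribed angles make whole modules collide
        moved = None
        for gap_factor in (1.0, 1.4, 1.9, 2.6, 3.5):
            gap = (linker_n + 1) * 1.0 * gap_factor
            p_start = a + gap * u
            t = p_start - R @ mod.atom(span.cys1, "CA").position
            cand = mod.with_coords(mod.coords @ R.T + t)
            new_ca = cand.coords[cand.select(atom_names=("CA",))]
            ok = True
            for prev, prev_span in zip(placed, spans):
                oc_idx = [i for i in prev.select(atom_names=("CA",))
                          if prev.atoms[i].residue_number not in
                          (prev_span.cys4, prev_span.cys4 - 1)]
                oc = prev.coords[oc_idx]
                near_idx = [i for i in cand.select(atom_names=("CA",))
                            if cand.atoms[i].residue_number not in
                            (span.cys1, span.cys1 + 1)]
                if cKDTree(oc).query(cand.coords[near_idx])[0].min() < clash_cutoff:
                    ok = False
                    break
            if ok:
                moved = cand
                break
        if moved is None:
            raise ValueError("non-adjacent modules clash at the requested angles")
        new_ca = moved.coords[moved.select(atom_names=("CA",))]

        # linker path: resample the perpendicular bow direction on clash.
        # The two attachment-end residues of the flanking modules are
        # necessarily close to the path and excluded from the check.
        def _ca_except_ends(s: Structure, sp: ModuleSpan, end: str) -> np.ndarray:
            skip = ({sp.cys4, sp.cys4 - 1} if end == "C" else {sp.cys1, sp.cys1 + 1})
            idx = [i for i in s.select(atom_names=("CA",))
                   if s.atoms[i].residue_number not in skip]
            return s.coords[idx]

        fixed = [s.coords[s.select(atom_names=("CA",))] for s in placed[:-1]]
        fixed.append(_ca_except_ends(placed[-1], spans[k], "C"))
        fixed.append(_ca_except_ends(moved, span, "N"))
        tree = cKDTree(np.vstack(fixed))
        block = None
        for attempt in range(max_tries):
            w = rng.normal(size=3)
            w /= np.linalg.norm(w)
            cand = _linker_atoms(1, 1, a, p_start, linker_n, w)
            ca_pts = np.array([at.position for at in cand if at.name == "CA"])
            if tree.query(ca_pts)[0].min() >= 3.0:
                block = cand
                break
        if block is None:
            raise ValueError("could not route linker without clashes")
        linker_atom_blocks.append(block)
        placed.append(moved)
        spans.append(span)
        frames.append(principal_frame(moved, span))

    # renumber consecutively and assemble
    out_atoms: list[Atom] = []
    new_spans: list[ModuleSpan] = []
    serial = 1
    resnum = 0
    used_names: set[str] = set()
    for k, (struct, span) in enumerate(zip(placed, spans)):
        res_map: dict[int, int] = {}
        for at in struct.atoms:
            if at.residue_number not in res_map:
                resnum += 1
                res_map[at.residue_number] = resnum
            out_atoms.append(Atom(serial, at.name, res_map[at.residue_number],
                                  at.residue_name, at.element, at.position.copy()))
            serial += 1
        name = span.name
        while name in used_names:
            name = f"{name}_{k + 1}"
        used_names.add(name)
        new_spans.append(ModuleSpan(
            name=name,
            cys1=res_map[span.cys1], cys4=res_map[span.cys4],
            ref_atom=(res_map[span.ref_atom[0]], span.ref_atom[1])))
        if k < len(linker_atom_blocks):
            n_link = len({a.residue_number for a in linker_atom_blocks[k]})
            for at in linker_atom_blocks[k]:
                out_atoms.append(Atom(serial, at.name,
                                      resnum + at.residue_number,
                                      at.residue_name, at.element,
                                      at.position.copy()))
                serial += 1
            resnum += n_link
    chain = Structure(out_atoms, label="+".join(s.name for s in new_spans))
    return chain, Architecture(new_spans)


def simulate_curve(structure, s_grid: np.ndarray, rel_noise: float = 0.02,
                   counts_scale: float | None = None, seed: int = 0,
                   representation: str = "heavy_atoms") -> ScatteringCurve:
    """Noisy Debye curve: sigma(s) = rel_noise * I(s) * (1 + s/s_max), observed
    intensity Normal(I, sigma).  rel_noise = 0 returns the exact curve."""
    from .saxs import debye_curve

    if rel_noise < 0:
        raise ValueError("rel_noise must be >= 0")
    base = debye_curve(structure, s_grid, representation=representation)
    if rel_noise == 0:
        return base
    rng = np.random.default_rng(seed)
    sigma = rel_noise * np.abs(base.I) * (1.0 + base.s / base.s.max())
    sigma = np.maximum(sigma, 1e-6 * float(np.max(np.abs(base.I))))
    I = base.I + rng.normal(size=base.I.shape) * sigma
    return ScatteringCurve(base.s, I, sigma, label=getattr(structure, "label", ""))


def synth_noe(structure: Structure, arch: Architecture, cutoff: float = 5.0,
              per_junction_max: int | None = None, seed: int = 0,
              min_residue_sep: int = 2, include_intra: bool = True) -> RestraintList:
    """Contact-derived NOE list: backbone heavy-atom pairs closer than
    ``cutoff`` (residue separation >= ``min_residue_sep``) become upper-bound
    restraints at d + 0.5 Angstrom.  Per-category counts are reported in
    ``meta['counts']``."""
    from .concat import count_intermodular

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(seed)
    idx = structure.select(atom_names=("N", "CA", "C", "O"))
    coords = structure.coords[idx]
    tree = cKDTree(coords)
    restraints: list[Restraint] = []
    seen: set[frozenset] = set()
    for i, j in sorted(tree.query_pairs(cutoff)):
        ai = structure.atoms[idx[i]]
        aj = structure.atoms[idx[j]]
        if abs(ai.residue_number - aj.residue_number) < min_residue_sep:
            continue
        if not include_intra:
            la = arch.locate(ai.residue_number)
            lb = arch.locate(aj.residue_number)
            if la == lb and la[0] == "module":
                continue
        key = frozenset((ai.key, aj.key))
        if key in seen:
            continue
        seen.add(key)
        d = float(np.linalg.norm(ai.position - aj.position))
        restraints.append(Restraint(ai.key, aj.key, d + 0.5))
    if per_junction_max is not None:
        by_cat: dict[tuple, list[Restraint]] = {}
        for r in restraints:
            la = arch.locate(r.atom_a[0])
            lb = arch.locate(r.atom_b[0])
            by_cat.setdefault((la, lb), []).append(r)
        kept: list[Restraint] = []
        for cat, rs in sorted(by_cat.items(), key=lambda kv: str(kv[0])):
            if len(rs) > per_junction_max:
                sel = rng.choice(len(rs), size=per_junction_max, replace=False)
                rs = [rs[i] for i in sorted(sel)]
            kept.extend(rs)
        restraints = kept
    rlist = RestraintList(restraints, label="synthetic")
    rlist.meta["counts"] = count_intermodular(rlist, arch)["totals"]
    return rlist


def jitter_ensemble(structure: Structure, amplitude: float, n: int,
                    seed: int = 0) -> Ensemble:
    """n copies of a structure with i.i.d. Gaussian displacement of the given
    amplitude (Angstrom, per coordinate)."""
    if amplitude < 0 or n < 1:
        raise ValueError("amplitude must be >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    coords = structure.coords
    confs = [structure.with_coords(coords + amplitude * rng.normal(size=coords.shape))
             for _ in range(n)]
    return Ensemble(confs, label=f"{structure.label}-jitter")
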