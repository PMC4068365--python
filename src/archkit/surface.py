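"""Solvent-accessible surface area (SASA), inter-module buried area, and
inter-module contact / salt-bridge detection.

SASA uses the Shrake-Rupley algorithm with a deterministic golden-spiral
point distribution, so repeated runs give identical areas.  Heavy atoms only
by default (matching typical web-server behaviour); hydrogens can be included
via ``include_hydrogens``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Architecture, ModuleSpan, Structure

__all__ = ["SasaResult", "Contact", "sasa", "buried_area", "find_contacts",
           "DEFAULT_RADII"]

# van der Waals radii (Angstrom)
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "D": 1.20}


@dataclass
class SasaResult:
    per_atom: np.ndarray          # Angstrom^2, aligned with the atom subset used
    atom_indices: list[int]       # indices into the input structure
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(np.sum(self.per_atom))


@dataclass
class Contact:
    atom_i: tuple[int, str]
    atom_j: tuple[int, str]
    distance: float
    salt_bridge: bool = False


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, nearly uniform points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960,
         radii: dict[str, float] | None = None,
         include_hydrogens: bool = False,
         atom_indices: list[int] | None = None) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is inflated by the probe radius; the exposed fraction is the
    fraction of ``n_points`` golden-spiral points on the inflated sphere not
    inside any neighbouring inflated sphere.
    """
    table = dict(DEFAULT_RADII)
    if radii:
        table.update(radii)
    if atom_indices is None:
        atom_indices = (list(range(len(structure))) if include_hydrogens
                        else structure.select(heavy_only=True))
    if not atom_indices:
        raise ValueError("no atoms selected for SASA")
    atoms = [structure.atoms[i] for i in atom_indices]
    for a in atoms:
        if a.element.upper() not in table:
            raise ValueError(f"unknown element {a.element!r}; supply a radius")
    centers = np.array([a.position for a in atoms])
    rad = np.array([table[a.element.upper()] + probe for a in atoms])
    sphere = _golden_spiral(n_points)
    tree = cKDTree(centers)
    rmax = float(rad.max())
    areas = np.empty(len(atoms))
    for i, (c, ri) in enumerate(zip(centers, rad)):
        nbrs = [j for j in tree.query_ball_point(c, ri + rmax) if j != i]
        pts = c + ri * sphere
        if nbrs:
            nc = centers[nbrs]
            nr = rad[nbrs]
            d2 = np.sum((pts[:, None, :] - nc[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nr ** 2)[None, :], axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        areas[i] = 4.0 * np.pi * ri * ri * exposed / n_points
    return SasaResult(per_atom=areas, atom_indices=list(atom_indices),
                      probe_radius=probe, n_sphere_points=n_points)


def _extended_spans(arch: Architecture, junction: int) -> tuple[range, range]:
    """Extended half-module boundaries used for buried-area accounting:
    the N-side module takes one residue before its Cys(I) through three
    residues after its Cys(IV); the C-side module takes the third residue
    before its Cys(I) through one residue after its Cys(IV)."""
    mi = arch.modules[junction]
    mj = arch.modules[junction + 1]
    span_i = range(mi.cys1 - 1, mi.cys4 + 3 + 1)
    span_j = range(mj.cys1 - 3, mj.cys4 + 1 + 1)
    return span_i, span_j


def buried_area(structure: Structure, arch: Architecture, junction: int,
                probe: float = 1.4, n_points: int = 960,
                radii: dict[str, float] | None = None) -> float:
    """Surface area (Angstrom^2) buried between two consecutive modules:
    SA(half_i) + SA(half_j) - SA(both), each half evaluated in isolation,
    with the extended-boundary residue rule splitting the linker near its
    midpoint.  Requires a linker long enough that the extended spans do not
    share residues (>= 6 residues between the boundary cysteines)."""
    if not 0 <= junction < len(arch) - 1:
        raise ValueError("junction index out of range")
    span_i, span_j = _extended_spans(arch, junction)
    shared = set(span_i) & set(span_j)
    if shared:
        linker_n = arch.modules[junction + 1].cys1 - arch.modules[junction].cys4 - 1
        raise ValueError(
            f"extended half-module spans share residues {sorted(shared)} "
            f"(linker of {linker_n} residues is too short for the boundary rule)")
    idx_i = structure.select(residues=span_i, heavy_only=True)
    idx_j = structure.select(residues=span_j, heavy_only=True)
    if not idx_i or not idx_j:
        raise ValueError("extended spans not resolvable in structure")
    kw = dict(probe=probe, n_points=n_points, radii=radii)
    sa_i = sasa(structure, atom_indices=idx_i, **kw).total
    sa_j = sasa(structure, atom_indices=idx_j, **kw).total
    sa_ij = sasa(structure, atom_indices=idx_i + idx_j, **kw).total
    return sa_i + sa_j - sa_ij


_BASIC = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
          ("HIS", "NE2"), ("HIS", "ND1")}
_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def find_contacts(structure: Structure, span_i: ModuleSpan, span_j: ModuleSpan,
                  vdw_cutoff: float = 4.0, saltbridge_cutoff: float = 4.0) -> list[Contact]:
    """Heavy-atom contacts across two disjoint spans; basic-to-acidic
    side-chain nitrogen/oxygen pairs within ``saltbridge_cutoff`` are labeled
    as salt bridges."""
    res_i = set(span_i.residues)
    res_j = set(span_j.residues)
    if res_i & res_j:
        raise ValueError("spans must be disjoint")
    idx_i = structure.select(residues=res_i, heavy_only=True)
    idx_j = structure.select(residues=res_j, heavy_only=True)
    if not idx_i or not idx_j:
        return []
    coords = structure.coords
    ti = cKDTree(coords[idx_i])
    tj = cKDTree(coords[idx_j])
    cutoff = max(vdw_cutoff, saltbridge_cutoff)
    out: list[Contact] = []
    pairs = [(ia, ib) for ia, nbrs in enumerate(ti.query_ball_tree(tj, cutoff))
             for ib in nbrs]
    for a, b in pairs:
        ai = structure.atoms[idx_i[a]]
        aj = structure.atoms[idx_j[b]]
        d = float(np.linalg.norm(ai.position - aj.position))
        ka = (ai.residue_name, ai.name)
        kb = (aj.residue_name, aj.name)
        is_sb = ((ka in _BASIC and kb in _ACIDIC) or (ka in _ACIDIC and kb in _BASIC)) \
            and d <= saltbridge_cutoff
        if d <= vdw_cutoff or is_sb:
            out.append(Contact(atom_i=ai.key, atom_j=aj.key, distance=d, salt_bridge=is_sb))
    out.sort(key=lambda c: (c.atom_i, c.atom_j))
    return out
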