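"""Building longer-fragment models from overlapping bi-module ensembles and
merging their NOE lists over a shared module.

Two overlapping fragments (A covering modules ...-X, B covering X-...) are
joined by superposing B onto A over the backbone of the common module X and
splicing B's chain after X.  The NOE lists are merged with a partition rule
keyed to the sequence midpoint of the common module, so no restraint can be
duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

from .core import (Architecture, Atom, BACKBONE_NAMES, Ensemble, Restraint,
                   RestraintList, Structure, closest_to_mean)
from .geometry import superpose

__all__ = ["concatenate", "merge_noe_lists", "count_intermodular",
           "ConcatResult"]


@dataclass
class ConcatResult:
    structure: Structure
    overlap_rmsd: float          # common-module backbone superposition, Angstrom
    pick_a: int
    pick_b: int


def concatenate(ens_a: Ensemble, ens_b: Ensemble, arch: Architecture,
                common: str, pick="closest_to_mean",
                rmsd_warn: float = 3.0) -> ConcatResult:
    """Join two fragment ensembles over a shared module.

    The chosen conformer of B is superposed onto the chosen conformer of A on
    the common module's backbone (N, CA, C, O); the output takes all atoms of
    A up to and including the common module plus the transformed atoms of B
    strictly after it.  The common module's coordinates therefore come from
    fragment A.  The backbone overlap rmsd is reported; above ``rmsd_warn``
    (Angstrom) a warning flags an incompatible overlap.
    """
    span = arch.module(common)
    if pick == "closest_to_mean":
        ia = closest_to_mean(ens_a)
        ib = closest_to_mean(ens_b)
    else:
        ia, ib = pick
    sa = ens_a[ia]
    sb = ens_b[ib]
    keys_a = [a.key for a in sa.atoms
              if a.residue_number in span.residues and a.name in BACKBONE_NAMES]
    keys_b = {a.key for a in sb.atoms
              if a.residue_number in span.residues and a.name in BACKBONE_NAMES}
    if not keys_a or set(keys_a) != keys_b:
        missing = sorted(set(keys_a) ^ keys_b)
        raise ValueError(f"common-module backbone mismatch between fragments: {missing[:5]}")
    ca = [sa.atom(*k).position for k in keys_a]
    cb = [sb.atom(*k).position for k in keys_a]
    R, t, rmsd = superpose(cb, ca)
    if rmsd > rmsd_warn:
        warnings.warn(f"incompatible overlap: common-module backbone rmsd "
                      f"{rmsd:.2f} A", stacklevel=2)
    out: list[Atom] = []
    serial = 1
    for a in sa.atoms:
        if a.residue_number <= span.cys4:
            out.append(Atom(serial, a.name, a.residue_number, a.residue_name,
                            a.element, a.position.copy()))
            serial += 1
    for b in sb.atoms:
        if b.residue_number > span.cys4:
            out.append(Atom(serial, b.name, b.residue_number, b.residue_name,
                            b.element, R @ b.position + t))
            serial += 1
    label = f"{ens_a.label}+{ens_b.label}" if (ens_a.label or ens_b.label) else "concat"
    return ConcatResult(Structure(out, label=label), rmsd, ia, ib)


def _merge_region(arch: Architecture, common_idx: int, midpoint: int,
                  residue: int, side: str) -> bool:
    kind, i = arch.locate(residue)
    if side == "A":
        if kind == "module":
            return i < common_idx or (i == common_idx and residue <= midpoint)
        if kind == "linker":
            return i < common_idx
        return False
    if kind == "module":
        return i > common_idx or (i == common_idx and residue > midpoint)
    if kind == "linker":
        return i >= common_idx
    return False


def merge_noe_lists(list_a: RestraintList, list_b: RestraintList,
                    arch: Architecture, common: str) -> RestraintList:
    """Merge two fragments' NOE lists over a shared module without duplication.

    A restraint from list A is kept iff both atoms lie in the preceding
    modules/linkers or the N-terminal (sequence) half of the common module;
    from list B iff both atoms lie in the C-terminal half, following linkers
    or following modules.  Restraints straddling the two kept regions are
    dropped and counted in ``meta['dropped_a'] / meta['dropped_b']``.
    """
    c = arch.module_index(common)
    span = arch.modules[c]
    midpoint = (span.cys1 + span.cys4) // 2
    kept: list[Restraint] = []
    dropped = {"A": 0, "B": 0}
    for side, rlist in (("A", list_a), ("B", list_b)):
        for r in rlist:
            if (_merge_region(arch, c, midpoint, r.atom_a[0], side)
                    and _merge_region(arch, c, midpoint, r.atom_b[0], side)):
                kept.append(r)
            else:
                dropped[side] += 1
    label = f"{list_a.label}+{list_b.label}"
    return RestraintList(kept, label=label,
                         meta={"dropped_a": dropped["A"], "dropped_b": dropped["B"],
                               "midpoint": midpoint})


def count_intermodular(rlist: RestraintList, arch: Architecture) -> dict:
    """Classify restraints by module architecture.

    Categories: 'intra' (both atoms in one module), 'n_module_to_linker' /
    'c_module_to_linker' (module to its following/preceding linker),
    'inter_module' (two different modules; per-junction counts reported for
    consecutive pairs), 'linker' (both in linkers), 'outside' (any atom not
    covered), 'other'.  Returns {'totals': {...}, 'per_junction': {...}}.
    """
    totals = {"intra": 0, "n_module_to_linker": 0, "c_module_to_linker": 0,
              "inter_module": 0, "linker": 0, "outside": 0, "other": 0}
    per_junction: dict[str, int] = {
        arch.junction_name(j): 0 for j in range(len(arch) - 1)}
    for r in rlist:
        (ka, ia) = arch.locate(r.atom_a[0])
        (kb, ib) = arch.locate(r.atom_b[0])
        if ka == "outside" or kb == "outside":
            totals["outside"] += 1
        elif ka == "module" and kb == "module":
            if ia == ib:
                totals["intra"] += 1
            else:
                totals["inter_module"] += 1
                lo, hi = sorted((ia, ib))
                if hi == lo + 1:
                    per_junction[arch.junction_name(lo)] += 1
        elif {ka, kb} == {"module", "linker"}:
            (mi, li) = (ia, ib) if ka == "module" else (ib, ia)
            if mi == li:
                totals["n_module_to_linker"] += 1   # module N-terminal of linker li
            elif mi == li + 1:
                totals["c_module_to_linker"] += 1   # module C-terminal of linker li
            else:
                totals["other"] += 1
        elif ka == "linker" and kb == "linker":
            totals["linker"] += 1
        else:
            totals["other"] += 1
    return {"totals": totals, "per_junction": per_junction}
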