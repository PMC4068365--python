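"""Domain types and readers/writers for structures, curves, restraints and architectures.

The package models beads-on-a-string multidomain proteins (tandem ~60-residue
modules joined by short linkers).  Coordinates are stored in Angstrom with
author residue numbering kept verbatim; module spans are inclusive on both
ends and addressed by their boundary cysteines.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml

BACKBONE_NAMES = ("N", "CA", "C", "O")

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "ModuleSpan",
    "Architecture",
    "Restraint",
    "RestraintList",
    "ScatteringCurve",
    "DistanceDistribution",
    "read_structure_ensemble",
    "write_structure",
    "read_curve",
    "write_curve",
    "read_noe_table",
    "write_noe_table",
    "read_architecture",
    "write_architecture",
    "closest_to_mean",
    "BACKBONE_NAMES",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom: author numbering, PDB-style names, position in Angstrom."""

    serial: int
    name: str
    residue_number: int
    residue_name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_number, self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


class Structure:
    """Ordered list of atoms of a single chain conformer."""

    def __init__(self, atoms: Sequence[Atom], label: str = "") -> None:
        atoms = list(atoms)
        if not atoms:
            raise ValueError("Structure requires at least one atom")
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[int, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate atom {dup[1]} in residue {dup[0]}")
        self.atoms = atoms
        self.label = label
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.residue_number, a.residue_name, a.element, c)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.label if label is None else label)

    def atom(self, residue_number: int, name: str) -> Atom:
        try:
            return self.atoms[self._index[(residue_number, name)]]
        except KeyError:
            raise KeyError(f"atom {name} of residue {residue_number} not found") from None

    def has_atom(self, residue_number: int, name: str) -> bool:
        return (residue_number, name) in self._index

    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for a in self.atoms:
            if not out or a.residue_number != out[-1]:
                out.append(a.residue_number)
        return out

    def select(
        self,
        residues: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
        predicate: Callable[[Atom], bool] | None = None,
    ) -> list[int]:
        """Indices of atoms passing all given filters, in structure order."""
        res = set(residues) if residues is not None else None
        names = set(atom_names) if atom_names is not None else None
        idx = []
        for i, a in enumerate(self.atoms):
            if res is not None and a.residue_number not in res:
                continue
            if names is not None and a.name not in names:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            if predicate is not None and not predicate(a):
                continue
            idx.append(i)
        return idx

    def subset(self, indices: Sequence[int], label: str = "") -> "Structure":
        return Structure([self.atoms[i] for i in indices], label or self.label)


class Ensemble:
    """Ordered conformers of one polypeptide sharing an identical atom list."""

    def __init__(self, conformers: Sequence[Structure], label: str = "") -> None:
        conformers = list(conformers)
        if not conformers:
            raise ValueError("Ensemble requires at least one conformer")
        ref = [(a.key, a.element) for a in conformers[0].atoms]
        for m, s in enumerate(conformers[1:], start=2):
            cur = [(a.key, a.element) for a in s.atoms]
            if cur != ref:
                for j, (r, c) in enumerate(zip(ref, cur)):
                    if r != c:
                        raise ValueError(
                            f"model {m} differs from model 1 at atom {j + 1}: "
                            f"expected {r[0][1]}/{r[0][0]}, got {c[0][1]}/{c[0][0]}"
                        )
                shorter = min(len(ref), len(cur))
                mism = ref[shorter] if len(ref) > len(cur) else cur[shorter]
                raise ValueError(
                    f"model {m} atom count {len(cur)} != {len(ref)}; first extra/missing "
                    f"atom {mism[0][1]} of residue {mism[0][0]}"
                )
        self.conformers = conformers
        self.label = label

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, i: int) -> Structure:
        return self.conformers[i]

    @property
    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate stack."""
        return np.stack([s.coords for s in self.conformers])


@dataclass(frozen=True)
class ModuleSpan:
    """One module: inclusive [cys1, cys4] span plus an off-axis reference atom."""

    name: str
    cys1: int
    cys4: int
    ref_atom: tuple[int, str]

    def __post_init__(self) -> None:
        if not self.cys1 < self.cys4:
            raise ValueError(f"module {self.name}: cys1 must precede cys4")
        if not self.cys1 <= self.ref_atom[0] <= self.cys4:
            raise ValueError(f"module {self.name}: ref_atom outside [cys1, cys4]")

    @property
    def residues(self) -> range:
        return range(self.cys1, self.cys4 + 1)


class Architecture:
    """Ordered, non-overlapping module spans; linkers are derived as the
    residues strictly between Cys(IV) of one module and Cys(I) of the next."""

    def __init__(self, modules: Sequence[ModuleSpan]) -> None:
        modules = list(modules)
        if not modules:
            raise ValueError("Architecture requires at least one module")
        for a, b in zip(modules, modules[1:]):
            if b.cys1 <= a.cys4:
                raise ValueError(f"modules {a.name} and {b.name} overlap or are out of order")
        self.modules = modules

    def __len__(self) -> int:
        return len(self.modules)

    def module(self, name: str) -> ModuleSpan:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(f"no module named {name!r}")

    def module_index(self, name: str) -> int:
        for i, m in enumerate(self.modules):
            if m.name == name:
                return i
        raise KeyError(f"no module named {name!r}")

    @property
    def linkers(self) -> list[range]:
        """Residue ranges strictly between consecutive modules (may be empty)."""
        return [
            range(a.cys4 + 1, b.cys1)
            for a, b in zip(self.modules, self.modules[1:])
        ]

    def junction_name(self, j: int) -> str:
        return f"{self.modules[j].name}/{self.modules[j + 1].name}"

    def locate(self, residue_number: int) -> tuple[str, int]:
        """('module', i), ('linker', i) (linker after module i), or ('outside', -1)."""
        for i, m in enumerate(self.modules):
            if m.cys1 <= residue_number <= m.cys4:
                return ("module", i)
        for i, lk in enumerate(self.linkers):
            if residue_number in lk:
                return ("linker", i)
        return ("outside", -1)


@dataclass(frozen=True)
class Restraint:
    """Upper-bound distance restraint between two named atoms (Angstrom)."""

    atom_a: tuple[int, str]
    atom_b: tuple[int, str]
    upper_bound: float

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError("upper_bound must be positive")
        if self.atom_a == self.atom_b:
            raise ValueError("restraint endpoints must differ")

    @property
    def pair(self) -> frozenset[tuple[int, str]]:
        return frozenset((self.atom_a, self.atom_b))


class RestraintList:
    """Deduplicated list of NOE upper-bound restraints."""

    def __init__(self, restraints: Sequence[Restraint], label: str = "",
                 meta: dict | None = None) -> None:
        pairs = [r.pair for r in restraints]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate unordered atom pair in restraint list")
        self.restraints = list(restraints)
        self.label = label
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)


class ScatteringCurve:
    """(s, I, sigma) triples on a strictly increasing momentum-transfer grid (nm^-1)."""

    def __init__(self, s: np.ndarray, I: np.ndarray, sigma: np.ndarray | None = None,
                 label: str = "") -> None:
        s = np.asarray(s, dtype=float)
        I = np.asarray(I, dtype=float)
        if s.ndim != 1 or s.shape != I.shape:
            raise ValueError("s and I must be 1-d arrays of equal length")
        if np.any(s < 0):
            raise ValueError("momentum transfer must be non-negative")
        if sigma is None:
            sigma = np.ones_like(I)
        else:
            sigma = np.asarray(sigma, dtype=float)
            if sigma.shape != s.shape:
                raise ValueError("sigma length mismatch")
            if np.any(sigma <= 0):
                raise ValueError("sigma must be positive")
        if np.any(np.diff(s) <= 0):
            order = np.argsort(s, kind="stable")
            if len(np.unique(s)) != len(s):
                raise ValueError("duplicate s values")
            warnings.warn("s grid not increasing; sorting", stacklevel=2)
            s, I, sigma = s[order], I[order], sigma[order]
        self.s = s
        self.I = I
        self.sigma = sigma
        self.label = label

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class DistanceDistribution:
    """Real-space pair-distance distribution p(r) on a grid in nm."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    peaks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.shape != self.p.shape:
            raise ValueError("r/p length mismatch")
        if np.any(self.p < -1e-8 * max(1.0, float(np.max(np.abs(self.p))))):
            raise ValueError("p(r) must be non-negative")

    @property
    def rg(self) -> float:
        """Rg (nm) from the second moment of p(r)."""
        norm = np.trapezoid(self.p, self.r)
        if norm <= 0:
            return 0.0
        return float(np.sqrt(np.trapezoid(self.p * self.r**2, self.r) / (2.0 * norm)))

    @property
    def i0(self) -> float:
        return float(4.0 * np.pi * np.trapezoid(self.p, self.r))


# ---------------------------------------------------------------------------
# structure I/O (PDB via gemmi)
# ---------------------------------------------------------------------------

def _from_gemmi(st) -> Ensemble:
    conformers = []
    for model in st:
        atoms = []
        for chain in model:
            for res in chain:
                for at in res:
                    if at.altloc not in ("", "A", "\x00"):
                        continue  # first altloc kept
                    atoms.append(Atom(
                        serial=at.serial,
                        name=at.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    ))
        if atoms:
            conformers.append(Structure(atoms, label=str(model.num)))
    if not conformers:
        raise ValueError("no coordinates found in PDB input")
    return Ensemble(conformers, label=st.name or "")


def read_structure_ensemble(pdb_text: str) -> Ensemble:
    """Parse a (multi-MODEL) PDB string into an Ensemble.

    Hydrogens are retained; only the first altloc is kept; a single chain is
    assumed.  Models with inconsistent atom sets raise with the first
    mismatching atom named.
    """
    import gemmi

    if not pdb_text.strip():
        raise ValueError("empty PDB input")
    st = gemmi.read_pdb_string(pdb_text)
    return _from_gemmi(st)


def _to_gemmi(ensemble: Ensemble):
    import gemmi

    st = gemmi.Structure()
    st.name = ensemble.label or "archkit"
    for i, conf in enumerate(ensemble.conformers, start=1):
        model = gemmi.Model(i)
        chain = gemmi.Chain("A")
        res = None
        for a in conf.atoms:
            if res is None or res.seqid.num != a.residue_number:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                chain.add_residue(res)
                res = chain[-1]
            at = gemmi.Atom()
            at.name = a.name
            at.serial = a.serial
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.position)
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(obj: Structure | Ensemble, path) -> None:
    """Write a Structure or Ensemble as fixed-column PDB (MODEL/ENDMDL for >1)."""
    ens = obj if isinstance(obj, Ensemble) else Ensemble([obj], label=obj.label)
    st = _to_gemmi(ens)
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def structure_to_pdb_string(obj: Structure | Ensemble) -> str:
    ens = obj if isinstance(obj, Ensemble) else Ensemble([obj], label=obj.label)
    return _to_gemmi(ens).make_pdb_string()


# ---------------------------------------------------------------------------
# scattering-curve I/O (whitespace 2-3 column text, '#' comments)
# ---------------------------------------------------------------------------

def read_curve(text: str, label: str = "") -> ScatteringCurve:
    rows = []
    for ln, line in enumerate(io.StringIO(text), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"line {ln}: expected at least 2 columns")
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError:
            raise ValueError(f"line {ln}: non-numeric value") from None
        rows.append(vals)
    if not rows:
        raise ValueError("no data rows in curve")
    s = np.array([r[0] for r in rows])
    I = np.array([r[1] for r in rows])
    if all(len(r) >= 3 for r in rows):
        sigma = np.array([r[2] for r in rows])
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
    else:
        sigma = None
    return ScatteringCurve(s, I, sigma, label=label)


def write_curve(curve: ScatteringCurve, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# s(nm^-1)  I  sigma\n")
        for s, I, sg in zip(curve.s, curve.I, curve.sigma):
            fh.write(f"{s:.8e} {I:.8e} {sg:.8e}\n")


# ---------------------------------------------------------------------------
# NOE restraint tables
# ---------------------------------------------------------------------------

def read_noe_table(text: str, dialect: str = "upl", label: str = "") -> RestraintList:
    """Parse an upper-limit distance-restraint table.

    dialect 'upl': ``resno resname atomname resno resname atomname upper``;
    dialect 'tsv': ``resno_a atom_a resno_b atom_b upper`` (tab or space).
    Duplicate unordered atom pairs are collapsed keeping the smaller bound;
    the number of collapsed rows is reported in ``meta['collapsed']``.
    """
    if dialect not in ("upl", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    best: dict[frozenset, Restraint] = {}
    collapsed = 0
    for ln, line in enumerate(io.StringIO(text), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if dialect == "upl":
                if len(parts) < 7:
                    raise ValueError("expected 7 columns")
                a = (int(parts[0]), parts[2])
                b = (int(parts[3]), parts[5])
                ub = float(parts[6])
            else:
                if len(parts) < 5:
                    raise ValueError("expected 5 columns")
                a = (int(parts[0]), parts[1])
                b = (int(parts[2]), parts[3])
                ub = float(parts[4])
            r = Restraint(a, b, ub)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"line {ln}: malformed restraint row ({exc})") from None
        key = r.pair
        if key in best:
            collapsed += 1
            if r.upper_bound < best[key].upper_bound:
                best[key] = r
        else:
            best[key] = r
    return RestraintList(list(best.values()), label=label, meta={"collapsed": collapsed})


_RESNAME_FALLBACK = "UNK"


def write_noe_table(rlist: RestraintList, path, dialect: str = "upl",
                    resnames: dict[int, str] | None = None) -> None:
    resnames = resnames or {}
    with open(path, "w") as fh:
        for r in rlist:
            if dialect == "upl":
                na = resnames.get(r.atom_a[0], _RESNAME_FALLBACK)
                nb = resnames.get(r.atom_b[0], _RESNAME_FALLBACK)
                fh.write(f"{r.atom_a[0]:5d} {na:4s} {r.atom_a[1]:5s} "
                         f"{r.atom_b[0]:5d} {nb:4s} {r.atom_b[1]:5s} {r.upper_bound:8.3f}\n")
            elif dialect == "tsv":
                fh.write(f"{r.atom_a[0]}\t{r.atom_a[1]}\t{r.atom_b[0]}\t"
                         f"{r.atom_b[1]}\t{r.upper_bound:.3f}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# architecture config (YAML)
# ---------------------------------------------------------------------------

def read_architecture(text: str) -> Architecture:
    """Architecture from YAML: ``modules: [{name, cys1, cys4, ref_residue, ref_atom}]``."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "modules" not in doc:
        raise ValueError("architecture YAML must contain a 'modules' list")
    spans = []
    for m in doc["modules"]:
        spans.append(ModuleSpan(
            name=str(m["name"]),
            cys1=int(m["cys1"]),
            cys4=int(m["cys4"]),
            ref_atom=(int(m["ref_residue"]), str(m.get("ref_atom", "CA"))),
        ))
    return Architecture(spans)


def write_architecture(arch: Architecture, path) -> None:
    doc = {"modules": [
        {"name": m.name, "cys1": m.cys1, "cys4": m.cys4,
         "ref_residue": m.ref_atom[0], "ref_atom": m.ref_atom[1]}
        for m in arch.modules
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# representative conformer
# ---------------------------------------------------------------------------

def closest_to_mean(ensemble: Ensemble,
                    selection: Callable[[Atom], bool] | Sequence[int] | None = None,
                    mode: str = "pairwise") -> int:
    """Index of the conformer most representative of the ensemble average.

    mode 'pairwise' (default): minimal mean pairwise RMSD to the other members
    after optimal superposition on the selection.  mode 'to_mean': minimal RMSD
    to the coordinate-mean structure.  Ties break to the lowest index.
    """
    from .geometry import superpose

    ref = ensemble.conformers[0]
    if selection is None:
        idx = list(range(len(ref)))
    elif callable(selection):
        idx = ref.select(predicate=selection)
    else:
        idx = list(selection)
    if not idx:
        raise ValueError("empty atom selection")
    stacks = ensemble.coords[:, idx, :]
    n = len(stacks)
    if n == 1:
        return 0
    if mode == "pairwise":
        score = np.zeros(n)
        for i in range(n):
            for j in range(i + 1, n):
                _, _, rmsd = superpose(stacks[i], stacks[j])
                score[i] += rmsd
                score[j] += rmsd
        score /= (n - 1)
    elif mode == "to_mean":
        aligned = [stacks[0] - stacks[0].mean(axis=0)]
        for i in range(1, n):
            rot, t, _ = superpose(stacks[i], aligned[0])
            aligned.append(stacks[i] @ rot.T + t)
        mean = np.mean(aligned, axis=0)
        score = np.array([superpose(c, mean)[2] for c in stacks])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return int(np.argmin(np.round(score, 12)))
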