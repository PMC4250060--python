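"""Structures, trajectories and atom selections.

This module provides the shared data model consumed by every analysis
stage: a lightweight :class:`Structure` (atoms + one coordinate set), a
:class:`Trajectory` (time-ordered frames bound to a topology), and a
small deterministic selection grammar (:class:`SelectionSpec`).

File parsing is delegated to MDAnalysis; the classes here are plain
containers so that analysis code never touches a reader object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "SelectionSpec",
    "SelectionError",
    "StructureParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "resolve_selection",
]

# Standard amino-acid residue names (used by the "protein" keyword).
PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL HSD HSE HSP MSE".split()
)

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection expression is malformed or unresolvable."""


@dataclass(frozen=True)
class Atom:
    """One atom record: identity only, coordinates live on the Structure."""

    name: str
    element: str
    resname: str
    resid: int
    chain: str
    occupancy: float = 1.0


@dataclass
class Structure:
    """A set of atoms with a single coordinate set (Å).

    Residue numbering follows the author numbering of the source file;
    altloc duplicates are resolved at read time (highest occupancy,
    first record on a tie).
    """

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3), Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.atoms), 3)
        if len(self.atoms) == 0:
            raise StructureParseError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureParseError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def select(self, expression: str) -> np.ndarray:
        return resolve_selection(self, SelectionSpec(expression))

    def subset(self, indices: np.ndarray) -> "Structure":
        indices = np.asarray(indices, dtype=int)
        return Structure(
            [self.atoms[i] for i in indices],
            self.coords[indices].copy(),
            dict(self.metadata),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(list(self.atoms), np.array(coords, dtype=float), dict(self.metadata))

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain, resid, resname) tuples in order of first appearance."""
        seen: dict[tuple[str, int], str] = {}
        out = []
        for a in self.atoms:
            key = (a.chain, a.resid)
            if key not in seen:
                seen[key] = a.resname
                out.append((a.chain, a.resid, a.resname))
        return out


@dataclass
class Trajectory:
    """Time-ordered coordinate frames sharing one topology.

    ``dt`` is the frame spacing in ps; frame times are ``i * dt``.
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    dt: float  # ps
    temperature: float | None = None  # K

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom "
                f"count {self.topology.n_atoms}"
            )
        if self.frames.shape[0] == 0:
            raise ValueError("trajectory has zero frames")
        if not self.dt > 0:
            raise ValueError("dt must be positive (ps)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.dt

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def subset_atoms(self, indices: np.ndarray) -> "Trajectory":
        indices = np.asarray(indices, dtype=int)
        return Trajectory(
            self.topology.subset(indices),
            self.frames[:, indices].copy(),
            self.dt,
            self.temperature,
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA2", "SE"}


def _element_from_name(name: str) -> str:
    """Infer element from a PDB atom name when no element column exists."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    # Protein atoms: first alphabetic character is the element (C, N, O, S).
    return stripped[0].upper()


def _universe_to_structure(u, source: str) -> Structure:
    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise StructureParseError(f"{source}: empty structure")
    names = atoms.names
    resnames = atoms.resnames
    resids = atoms.resids
    try:
        chains = atoms.chainIDs
    except AttributeError:
        chains = atoms.segids
    chains = ["A" if not str(c).strip() else str(c).strip() for c in chains]
    try:
        occ = atoms.occupancies
    except AttributeError:
        occ = np.ones(n)
    try:
        elements = [str(e).strip() for e in atoms.elements]
    except AttributeError:
        elements = ["" for _ in range(n)]
    try:
        altlocs = [str(a).strip() for a in atoms.altLocs]
    except AttributeError:
        altlocs = ["" for _ in range(n)]

    records = []
    for i in range(n):
        el = elements[i] or _element_from_name(str(names[i]))
        records.append(
            (
                Atom(str(names[i]), el.upper(), str(resnames[i]), int(resids[i]), chains[i], float(occ[i])),
                altlocs[i],
                i,
            )
        )

    # Altloc resolution: within each (chain, resid, name) group keep the
    # highest-occupancy record, first on tie.
    best: dict[tuple[str, int, str, str], tuple[Atom, str, int]] = {}
    order: list[tuple[str, int, str, str]] = []
    for rec in records:
        atom = rec[0]
        key = (atom.chain, atom.resid, atom.resname, atom.name)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif atom.occupancy > best[key][0].occupancy:
            best[key] = rec
    kept = [best[k] for k in order]
    idx = np.array([r[2] for r in kept], dtype=int)
    return Structure(
        [r[0] for r in kept],
        atoms.positions[idx].astype(float),
        {"source": source},
    )


def read_structure(path: str | Path) -> Structure:
    """Read a PDB (or other MDAnalysis-readable) file into a Structure.

    Altloc duplicates are collapsed to the highest-occupancy site;
    chain ids and author residue numbering are preserved.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - reader errors are diverse
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    return _universe_to_structure(u, str(path))


_TIMED_FORMATS = {".dcd", ".xtc", ".trr"}


def read_trajectory(
    path: str | Path,
    topology: Structure,
    dt: float | None = None,
    temperature: float | None = None,
) -> Trajectory:
    """Read a coordinate trajectory against a topology Structure.

    Supports one binary dialect (DCD/XTC/TRR) plus multi-model PDB and
    XYZ fallbacks.  Formats that carry no time information (PDB, XYZ)
    require an explicit ``dt`` in ps.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except Exception as exc:  # noqa: BLE001
        raise StructureParseError(f"cannot parse trajectory {path}: {exc}") from exc

    n_file = u.trajectory.n_atoms
    if n_file != topology.n_atoms:
        raise StructureParseError(
            f"atom-count mismatch: trajectory {path} has {n_file} atoms, "
            f"topology has {topology.n_atoms}"
        )
    frames = np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)
    if frames.shape[0] == 0:
        raise StructureParseError(f"{path}: zero frames")

    if dt is None:
        if path.suffix.lower() in _TIMED_FORMATS:
            dt = float(u.trajectory.ts.dt)
        else:
            raise ValueError(
                f"frame spacing dt is not derivable from {path.suffix} files; "
                "pass dt explicitly (ps)"
            )
    return Trajectory(topology, frames, float(dt), temperature)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _to_universe(structure: Structure, frames: np.ndarray):
    import MDAnalysis as mda

    n = structure.n_atoms
    reskeys: list[tuple[str, int]] = []
    res_index = []
    for a in structure.atoms:
        key = (a.chain, a.resid)
        if not reskeys or reskeys[-1] != key:
            reskeys.append(key)
        res_index.append(len(reskeys) - 1)
    n_res = len(reskeys)
    seg_of_res: list[str] = []
    seen_chain: list[str] = []
    for chain, _ in reskeys:
        if chain not in seen_chain:
            seen_chain.append(chain)
        seg_of_res.append(chain)
    u = mda.Universe.empty(
        n,
        n_residues=n_res,
        n_segments=len(seen_chain),
        atom_resindex=np.array(res_index),
        residue_segindex=np.array([seen_chain.index(c) for c in seg_of_res]),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in structure.atoms])
    u.add_TopologyAttr("elements", [a.element for a in structure.atoms])
    u.add_TopologyAttr("occupancies", [a.occupancy for a in structure.atoms])
    u.add_TopologyAttr("altLocs", [""] * n)
    u.add_TopologyAttr("tempfactors", [0.0] * n)
    u.add_TopologyAttr("resnames", [structure.atoms[[i for i, r in enumerate(res_index) if r == k][0]].resname for k in range(n_res)])
    u.add_TopologyAttr("resids", [rid for _, rid in reskeys])
    u.add_TopologyAttr("chainIDs", [structure.atoms[i].chain for i in range(n)])
    u.add_TopologyAttr("segids", seen_chain)
    u.load_new(np.asarray(frames, dtype=np.float32))
    return u


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure to PDB (or XYZ, by extension)."""
    write_trajectory(
        Trajectory(structure, structure.coords[None, :, :], dt=1.0), path
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as a multi-model PDB or XYZ file (by extension)."""
    import MDAnalysis as mda

    path = Path(path)
    u = _to_universe(traj.topology, traj.frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, multiframe=traj.n_frames > 1) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionSpec:
    """A selection expression in a small grammar.

    Clauses: ``chain <id>[,<id>..]``, ``resid <n>|<a>-<b>[,..]``,
    ``name <NAME>[,..]``, and the keywords ``ca``, ``backbone``,
    ``heavy``, ``sidechain-heavy``, ``protein``, ``all``.  Clauses
    combine with ``and``, ``or``, ``not`` and parentheses (``not``
    binds tightest, then ``and``).
    """

    expression: str


def _tokenize(expr: str) -> list[str]:
    out: list[str] = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], structure: Structure):
        self.tokens = tokens
        self.pos = 0
        self.s = structure
        n = structure.n_atoms
        self._names = np.array([a.name for a in structure.atoms])
        self._elements = np.array([a.element for a in structure.atoms])
        self._chains = np.array([a.chain for a in structure.atoms])
        self._resids = np.array([a.resid for a in structure.atoms])
        self._resnames = np.array([a.resname for a in structure.atoms])
        self._n = n

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:  # or-level
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:  # and-level
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.clause()

    def _values(self) -> list[str]:
        vals = self.next().split(",")
        # allow space-separated continuation: "resid 1 2 3"
        while self.peek() is not None and self.peek() not in {
            "and",
            "or",
            "not",
            "(",
            ")",
            "chain",
            "resid",
            "name",
            "resname",
        } and not self._is_keyword(self.peek()):
            vals.extend(self.next().split(","))
        return [v for v in vals if v]

    @staticmethod
    def _is_keyword(tok: str | None) -> bool:
        return tok in {"ca", "backbone", "heavy", "sidechain-heavy", "side-chain-heavy", "protein", "all"}

    def clause(self) -> np.ndarray:
        tok = self.next().lower()
        if tok == "chain":
            vals = set(self._values())
            unknown = vals - set(self._chains)
            if unknown:
                raise SelectionError(f"unknown chain id(s): {sorted(unknown)}")
            return np.isin(self._chains, sorted(vals))
        if tok == "resid":
            mask = np.zeros(self._n, dtype=bool)
            present = set(self._resids.tolist())
            for v in self._values():
                if "-" in v[1:]:
                    cut = v.index("-", 1)
                    lo, hi = int(v[:cut]), int(v[cut + 1 :])
                    mask |= (self._resids >= lo) & (self._resids <= hi)
                elif ":" in v:
                    lo, hi = (int(x) for x in v.split(":", 1))
                    mask |= (self._resids >= lo) & (self._resids <= hi)
                else:
                    rid = int(v)
                    if rid not in present:
                        raise SelectionError(f"unknown residue index {rid}")
                    mask |= self._resids == rid
            return mask
        if tok == "name":
            vals = set(v.upper() for v in self._values())
            return np.isin(np.char.upper(self._names), sorted(vals))
        if tok == "resname":
            vals = set(v.upper() for v in self._values())
            return np.isin(np.char.upper(self._resnames), sorted(vals))
        if tok == "ca":
            return (np.char.upper(self._names) == "CA") & (self._elements != "H")
        if tok == "backbone":
            return np.isin(np.char.upper(self._names), sorted(BACKBONE_NAMES)) & (
                self._elements != "H"
            ) & np.isin(self._resnames, sorted(PROTEIN_RESNAMES))
        if tok == "heavy":
            return self._elements != "H"
        if tok in {"sidechain-heavy", "side-chain-heavy"}:
            return (
                (self._elements != "H")
                & ~np.isin(np.char.upper(self._names), sorted(BACKBONE_NAMES))
                & np.isin(self._resnames, sorted(PROTEIN_RESNAMES))
            )
        if tok == "protein":
            return np.isin(self._resnames, sorted(PROTEIN_RESNAMES))
        if tok == "all":
            return np.ones(self._n, dtype=bool)
        raise SelectionError(f"unknown selection token {tok!r}")


def resolve_selection(structure: Structure, spec: SelectionSpec | str) -> np.ndarray:
    """Resolve a selection to a sorted, deterministic atom index array.

    An empty result is legal and returned with a warning; unknown chain
    or residue references raise :class:`SelectionError`.
    """
    if isinstance(spec, str):
        spec = SelectionSpec(spec)
    tokens = _tokenize(spec.expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, structure).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(
            f"selection {spec.expression!r} matched no atoms", stacklevel=2
        )
    return idx
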