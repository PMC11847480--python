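"""Fixed-width PDB reading/writing, multi-model trajectories and atom selections.

The on-disk dialect is wwPDB v3.3 fixed-width ATOM/HETATM records.  Residue
numbers are kept exactly as found in the input (author numbering); insertion
codes are rejected rather than silently merged so that residue addressing
stays deterministic.  Trajectories are multi-model PDB files (MODEL/ENDMDL
blocks over one fixed topology) -- human-inspectable and diffable, which is
what the synthetic fixtures and the analysis stages need.

Selections use a small expression language::

    chain A and resid 70:82 and name CA
    (chain G and resid 1:40) or (chain R and name NZ)

``and`` binds tighter than ``or``; predicates are ``chain``, ``resid``
(single number, comma list, or inclusive ``start:end`` range), ``name`` and
``element``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PDBParseError",
    "TopologyMismatchError",
    "SelectionError",
    "FormatOverflowError",
    "AtomRecord",
    "Structure",
    "Trajectory",
    "DomainDefinition",
    "Selection",
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "write_trajectory",
    "resolve_selection",
]


class PDBParseError(ValueError):
    """Raised for malformed fixed-width PDB input."""


class TopologyMismatchError(ValueError):
    """Raised when trajectory models disagree on atom count or identity."""


class SelectionError(ValueError):
    """Raised when a selection predicate cannot be resolved."""


class FormatOverflowError(ValueError):
    """Raised when a value cannot be represented in the fixed-width format."""


#: standard atomic masses (u) for the elements the toolkit encounters
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,  # element calcium, not the CA atom name
}

DEFAULT_MASS = 12.011


@dataclass
class AtomRecord:
    """One ATOM/HETATM record (author numbering preserved verbatim)."""

    serial: int
    atom_name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    hetero: bool = False


def _guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (first alphabetic character)."""
    stripped = atom_name.strip()
    # two-character elements occupy columns 13-14 and are all-caps (FE, ZN...)
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


class Structure:
    """A topology: parallel arrays of atom attributes plus coordinates (Å)."""

    def __init__(
        self,
        serial: np.ndarray,
        atom_name: np.ndarray,
        element: np.ndarray,
        res_name: np.ndarray,
        res_seq: np.ndarray,
        chain_id: np.ndarray,
        coords: np.ndarray,
        b_factor: np.ndarray | None = None,
        occupancy: np.ndarray | None = None,
        hetero: np.ndarray | None = None,
    ):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.element = np.asarray(element, dtype=object)
        self.res_name = np.asarray(res_name, dtype=object)
        self.res_seq = np.asarray(res_seq, dtype=np.int64)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.b_factor = (
            np.zeros(n) if b_factor is None else np.asarray(b_factor, dtype=float)
        )
        self.occupancy = (
            np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=float)
        )
        self.hetero = (
            np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, dtype=bool)
        )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def chain_index(self) -> dict[str, np.ndarray]:
        """Map chain_id -> atom index array (file order)."""
        out: dict[str, np.ndarray] = {}
        for cid in dict.fromkeys(self.chain_id):  # preserves order
            out[cid] = np.flatnonzero(self.chain_id == cid)
        return out

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            atom_name=str(self.atom_name[i]),
            element=str(self.element[i]),
            res_name=str(self.res_name[i]),
            res_seq=int(self.res_seq[i]),
            chain_id=str(self.chain_id[i]),
            coords=self.coords[i].copy(),
            b_factor=float(self.b_factor[i]),
            occupancy=float(self.occupancy[i]),
            hetero=bool(self.hetero[i]),
        )

    def masses(self) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(str(e).upper(), DEFAULT_MASS) for e in self.element]
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.serial[idx],
            self.atom_name[idx],
            self.element[idx],
            self.res_name[idx],
            self.res_seq[idx],
            self.chain_id[idx],
            self.coords[idx],
            self.b_factor[idx],
            self.occupancy[idx],
            self.hetero[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        s = self.subset(np.arange(self.n_atoms))
        s.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return s

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain_id, res_seq) pairs in file order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.res_seq):
            seen[(str(c), int(r))] = None
        return list(seen)

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        groups: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chain_id, self.res_seq)):
            groups.setdefault((str(c), int(r)), []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}


@dataclass
class Trajectory:
    """Frame-ordered coordinate sets (n_frames, n_atoms, 3) over one topology."""

    topology: Structure
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"frames carry {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


# ----------------------------------------------------------------------
# Parsing
# ----------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    padded = line.rstrip("\n").ljust(80)
    try:
        serial = int(padded[6:11])
        name = padded[12:16].strip()
        altloc = padded[16]
        res_name = padded[17:20].strip()
        chain = padded[21]
        res_seq = int(padded[22:26])
        icode = padded[26]
        x = float(padded[30:38])
        y = float(padded[38:46])
        z = float(padded[46:54])
        occ_f = padded[54:60].strip()
        b_f = padded[60:66].strip()
        occ = float(occ_f) if occ_f else 1.0
        b = float(b_f) if b_f else 0.0
        element = padded[76:78].strip()
    except ValueError as exc:
        raise PDBParseError(
            f"malformed fixed-width ATOM/HETATM record at line {lineno}: {exc}"
        ) from exc
    if not name:
        raise PDBParseError(f"empty atom name at line {lineno}")
    if icode not in (" ", ""):
        raise PDBParseError(
            f"insertion code {icode!r} at line {lineno}: insertion codes are "
            "not supported (deterministic residue addressing requires plain "
            "author numbering)"
        )
    if not element:
        element = _guess_element(name)
    rec = AtomRecord(
        serial=serial,
        atom_name=name,
        element=element.upper(),
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain,
        coords=np.array([x, y, z]),
        b_factor=b,
        occupancy=occ,
        hetero=padded.startswith("HETATM"),
    )
    # stash altloc for the dedup pass; not part of the public record
    rec._altloc = altloc  # type: ignore[attr-defined]
    return rec


def _dedup_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy alternate location; ties resolve to 'A'."""
    best: dict[tuple[str, int, str], tuple[float, str, int]] = {}
    for i, rec in enumerate(records):
        alt = getattr(rec, "_altloc", " ")
        key = (rec.chain_id, rec.res_seq, rec.atom_name)
        if key not in best:
            best[key] = (rec.occupancy, alt, i)
        else:
            occ, balt, _ = best[key]
            if rec.occupancy > occ or (rec.occupancy == occ and alt == "A" != balt):
                best[key] = (rec.occupancy, alt, i)
    keep = sorted(i for (_, _, i) in best.values())
    return [records[i] for i in keep]


def _records_to_structure(records: list[AtomRecord]) -> Structure:
    return Structure(
        serial=np.array([r.serial for r in records]),
        atom_name=np.array([r.atom_name for r in records], dtype=object),
        element=np.array([r.element for r in records], dtype=object),
        res_name=np.array([r.res_name for r in records], dtype=object),
        res_seq=np.array([r.res_seq for r in records]),
        chain_id=np.array([r.chain_id for r in records], dtype=object),
        coords=np.array([r.coords for r in records]),
        b_factor=np.array([r.b_factor for r in records]),
        occupancy=np.array([r.occupancy for r in records]),
        hetero=np.array([r.hetero for r in records]),
    )


def read_pdb(path, include_hetatm: bool = False) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    Alternate locations keep the highest-occupancy copy (tie -> altloc 'A');
    HETATM records are skipped unless ``include_hetatm``.
    """
    records: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "ENDMDL":
                break
            if tag == "ATOM" or (tag == "HETATM" and include_hetatm):
                records.append(_parse_atom_line(line, lineno))
    if not records:
        raise PDBParseError(f"no ATOM records found in {path}")
    return _records_to_structure(_dedup_altlocs(records))


def read_trajectory(path, dt: float = 1.0, times: np.ndarray | None = None,
                    include_hetatm: bool = False) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Without explicit ``times``, frame times default to ``frame_index * dt``
    with ``dt`` in ns (default 1 ns, the snapshot spacing the analyses use).
    """
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    saw_model_kw = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                saw_model_kw = True
                current = []
            elif tag == "ENDMDL":
                if current:
                    models.append(current)
                current = None
            elif tag == "ATOM" or (tag == "HETATM" and include_hetatm):
                rec = _parse_atom_line(line, lineno)
                if current is None:
                    if saw_model_kw:
                        raise PDBParseError(
                            f"ATOM record outside MODEL block at line {lineno}"
                        )
                    current = []
                current.append(rec)
    if current:
        models.append(current)
    if not models:
        raise PDBParseError(f"no ATOM records found in {path}")

    models = [_dedup_altlocs(m) for m in models]
    n0 = len(models[0])
    for k, m in enumerate(models, start=1):
        if len(m) != n0:
            raise TopologyMismatchError(
                f"model {k} has {len(m)} atoms, expected {n0}"
            )
    topo = _records_to_structure(models[0])
    coords = np.array([[r.coords for r in m] for m in models])
    if times is None:
        times = np.arange(len(models), dtype=float) * float(dt)
    return Trajectory(topology=topo, coords=coords, times=np.asarray(times, float))


# ----------------------------------------------------------------------
# Writing
# ----------------------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # names shorter than 4 chars start in column 14 unless they begin with a
    # digit (e.g. 1HB) or are 4 characters wide
    if len(name) >= 4 or (name and name[0].isdigit()):
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)


def _atom_line(rec_tag: str, serial: int, name: str, res_name: str, chain: str,
               res_seq: int, xyz: np.ndarray, occ: float, b: float,
               element: str) -> str:
    if np.any(np.abs(xyz) >= 1e4):
        raise FormatOverflowError(
            f"coordinate magnitude >= 10^4 Å cannot be written in %8.3f "
            f"columns (atom serial {serial})"
        )
    return (
        f"{rec_tag:<6}{serial:>5} {_format_atom_name(name)} {res_name:<3.3s}"
        f" {chain:1.1s}{res_seq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2.2s}"
    )


def _structure_lines(structure: Structure, coords: np.ndarray | None = None,
                     b_factors: np.ndarray | None = None) -> list[str]:
    xyz = structure.coords if coords is None else np.asarray(coords, float)
    b = structure.b_factor if b_factors is None else np.asarray(b_factors, float)
    lines = []
    for i in range(structure.n_atoms):
        tag = "HETATM" if structure.hetero[i] else "ATOM"
        lines.append(
            _atom_line(
                tag,
                int(structure.serial[i]),
                str(structure.atom_name[i]),
                str(structure.res_name[i]),
                str(structure.chain_id[i]),
                int(structure.res_seq[i]),
                xyz[i],
                float(structure.occupancy[i]),
                float(b[i]),
                str(structure.element[i]),
            )
        )
    return lines


def write_pdb(structure: Structure, path, coords: np.ndarray | None = None,
              b_factors: np.ndarray | None = None,
              header_remarks: list[str] | None = None) -> None:
    """Write a structure (optionally with replacement coordinates/B column)."""
    lines: list[str] = []
    for remark in header_remarks or []:
        lines.append(f"REMARK   6 {remark}")
    lines.extend(_structure_lines(structure, coords, b_factors))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_trajectory(trajectory: Trajectory, path,
                     header_remarks: list[str] | None = None) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    lines: list[str] = []
    for remark in header_remarks or []:
        lines.append(f"REMARK   6 {remark}")
    for k in range(trajectory.n_frames):
        lines.append(f"MODEL     {k + 1:>4}")
        lines.extend(_structure_lines(trajectory.topology, trajectory.coords[k]))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Selections
# ----------------------------------------------------------------------

@dataclass
class Selection:
    """Resolved, sorted, unique atom indices plus the originating expression."""

    indices: np.ndarray
    expression: str
    empty: bool = field(init=False)

    def __post_init__(self):
        self.indices = np.unique(np.asarray(self.indices, dtype=int))
        self.empty = len(self.indices) == 0

    def __len__(self) -> int:
        return len(self.indices)


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelectionParser:
    """Recursive-descent parser: expr := term (or term)*, term := atom (and atom)*."""

    def __init__(self, structure: Structure, expression: str):
        self.s = structure
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.expression = expression

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self.pos != len(self.tokens):
            raise SelectionError(
                f"unexpected token {self.tokens[self.pos]!r} in "
                f"{self.expression!r}"
            )
        return mask

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise SelectionError(f"unexpected end of expression {self.expression!r}")
        self.pos += 1
        return tok

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() is not None and self._peek().lower() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek() is not None and self._peek().lower() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok = self._next()
        if tok == "(":
            mask = self._expr()
            if self._next() != ")":
                raise SelectionError(f"unbalanced parentheses in {self.expression!r}")
            return mask
        return self._predicate(tok.lower())

    def _values(self) -> list[str]:
        vals = self._next().split(",")
        return [v for v in vals if v]

    def _predicate(self, kind: str) -> np.ndarray:
        s = self.s
        if kind == "chain":
            vals = self._values()
            known = set(map(str, s.chain_id))
            for v in vals:
                if v not in known:
                    raise SelectionError(
                        f"unresolved selection: chain {v!r} not present "
                        f"(predicate 'chain {v}')"
                    )
            return np.isin(s.chain_id.astype(str), vals)
        if kind == "name":
            vals = self._values()
            known = set(map(str, s.atom_name))
            for v in vals:
                if v not in known:
                    raise SelectionError(
                        f"unresolved selection: atom name {v!r} not present "
                        f"(predicate 'name {v}')"
                    )
            return np.isin(s.atom_name.astype(str), vals)
        if kind == "element":
            vals = [v.upper() for v in self._values()]
            return np.isin(np.char.upper(s.element.astype(str)), vals)
        if kind == "resid":
            mask = np.zeros(s.n_atoms, dtype=bool)
            for v in self._values():
                part = v.replace("-", ":") if ":" not in v and "-" in v[1:] else v
                if ":" in part:
                    lo_s, hi_s = part.split(":")
                    lo, hi = int(lo_s), int(hi_s)
                    mask |= (s.res_seq >= lo) & (s.res_seq <= hi)
                else:
                    mask |= s.res_seq == int(part)
            return mask
        raise SelectionError(f"unknown predicate {kind!r} in {self.expression!r}")


def resolve_selection(structure: Structure, expression: str,
                      warn_empty: bool = True) -> Selection:
    """Resolve a selection expression to sorted unique atom indices.

    Pure function of (structure, expression).  Unknown chains or atom names
    raise :class:`SelectionError`; an empty combined selection is allowed but
    emits a warning.
    """
    mask = _SelectionParser(structure, expression).parse()
    sel = Selection(indices=np.flatnonzero(mask), expression=expression)
    if sel.empty and warn_empty:
        warnings.warn(f"selection {expression!r} resolved to zero atoms")
    return sel


@dataclass
class DomainDefinition:
    """A named set of inclusive residue ranges on one chain (e.g. gp130 D2)."""

    label: str
    chain_id: str
    residue_ranges: list[tuple[int, int]]

    def __post_init__(self):
        if not self.residue_ranges:
            raise ValueError(f"domain {self.label}: no residue ranges")
        spans = sorted((int(a), int(b)) for a, b in self.residue_ranges)
        for (a, b) in spans:
            if b < a:
                raise ValueError(f"domain {self.label}: empty range [{a}, {b}]")
        for (_, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError(f"domain {self.label}: overlapping ranges")
        self.residue_ranges = spans

    def resolve(self, structure: Structure) -> Selection:
        chain_mask = structure.chain_id.astype(str) == self.chain_id
        if not chain_mask.any():
            raise SelectionError(
                f"domain {self.label}: chain {self.chain_id!r} not in topology"
            )
        present = set(structure.res_seq[chain_mask].tolist())
        mask = np.zeros(structure.n_atoms, dtype=bool)
        for lo, hi in self.residue_ranges:
            missing = [r for r in range(lo, hi + 1) if r not in present]
            if missing:
                raise SelectionError(
                    f"domain {self.label}: residues {missing[:5]} absent from "
                    f"chain {self.chain_id}"
                )
            mask |= chain_mask & (structure.res_seq >= lo) & (structure.res_seq <= hi)
        return Selection(indices=np.flatnonzero(mask),
                         expression=f"domain {self.label}")
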