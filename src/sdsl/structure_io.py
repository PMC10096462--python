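"""PDB structure reading/writing, atom selection and site mutation.

The container here is deliberately minimal: a flat, ordered atom table plus
one coordinate frame per MODEL block. Occupancy is load-bearing — the
multistate ensemble writer stores rotamer weights in the occupancy column —
so it is carried through parsing verbatim.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyStructureError,
    IncompleteBackboneError,
    PDBParseError,
    QuerySyntaxError,
)

WATER_RESNAMES = frozenset({"HOH", "WAT"})
BACKBONE_NAMES = ("N", "CA", "C", "O")

__all__ = [
    "Atom",
    "StructureModel",
    "AtomSubset",
    "read_pdb",
    "write_pdb",
    "select",
    "mutate",
    "write_ensemble_pdb",
]


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    resname: str
    resnum: int
    chain: str
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False


@dataclass
class StructureModel:
    """A parsed structure: shared topology + one coordinate set per model."""

    atoms: list[Atom]
    models: list[np.ndarray]  # each (n_atoms, 3) float64, Å
    source_id: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def coords(self) -> np.ndarray:
        """Coordinates of the first model."""
        return self.models[0]

    def copy(self) -> "StructureModel":
        return StructureModel(
            atoms=[copy.copy(a) for a in self.atoms],
            models=[m.copy() for m in self.models],
            source_id=self.source_id,
        )

    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return i
        raise KeyError(f"no atom {chain}/{resnum}/{name}")

    def residue_indices(self, chain: str, resnum: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain == chain and a.resnum == resnum
        ]

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resnum, resname) triples."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resnum), a.resname)
        return [(c, r, n) for (c, r), n in seen.items()]

    def backbone_indices(self, chain: str, resnum: int) -> tuple[int, int, int]:
        """Indices of N, CA, C at a site; raises if any is absent."""
        idx = {}
        for i in self.residue_indices(chain, resnum):
            if self.atoms[i].name in ("N", "CA", "C"):
                idx[self.atoms[i].name] = i
        missing = [n for n in ("N", "CA", "C") if n not in idx]
        if missing:
            raise IncompleteBackboneError(
                f"site {chain}/{resnum} lacks backbone atom(s) {missing}"
            )
        return idx["N"], idx["CA"], idx["C"]


@dataclass
class AtomSubset:
    """An ordered, strictly-increasing index list into a StructureModel."""

    structure: StructureModel
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.size:
            if idx.min() < 0 or idx.max() >= self.structure.n_atoms:
                raise IndexError("subset index out of range")
            if len(np.unique(idx)) != len(idx):
                raise ValueError("subset indices must be unique")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def atoms(self) -> list[Atom]:
        return [self.structure.atoms[i] for i in self.indices]

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords[self.indices]


# ---------------------------------------------------------------------------
# PDB parsing

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray] | None:
    altloc = line[16:17]
    if altloc not in (" ", "", "A"):
        return None
    icode = line[26:27]
    if icode not in (" ", ""):
        raise PDBParseError(f"line {lineno}: insertion codes are unsupported")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21:22].strip() or "A"
        resnum = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed field ({exc})") from exc
    if not np.all(np.isfinite(xyz)):
        raise PDBParseError(f"line {lineno}: non-finite coordinates")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the first alphabetic character of the atom name
        stripped = name.lstrip("0123456789")
        element = stripped[:2].capitalize() if stripped[:2] in (
            "BR", "CU", "GD", "CL", "FE", "ZN", "MG", "MN", "NA",
        ) else stripped[:1].upper()
    atom = Atom(
        serial=serial,
        name=name,
        element=element.capitalize() if len(element) == 2 else element.upper(),
        resname=resname,
        resnum=resnum,
        chain=chain,
        occupancy=occ,
        bfactor=bfac,
        het=line.startswith("HETATM"),
    )
    return atom, xyz


def read_pdb(source: str | Path) -> StructureModel:
    """Parse PDB text (or a path to it) into a :class:`StructureModel`.

    ATOM and HETATM records are both read; alternate locations other than
    blank or 'A' are skipped; MODEL/ENDMDL blocks become coordinate frames
    sharing the first block's topology.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
        source_id = Path(source).name
    else:
        text = str(source)
        source_id = "<text>"

    atoms: list[Atom] = []
    model_coords: list[list[np.ndarray]] = []
    current: list[np.ndarray] | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current:
                model_coords.append(current)
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                model_coords.append(current)
                current = None
        elif rec in ("ATOM  ", "HETATM"):
            parsed = _parse_atom_line(line, lineno)
            if parsed is None:
                continue
            atom, xyz = parsed
            if current is None:
                current = []
            if not model_coords:
                atoms.append(atom)
            current.append(xyz)
    if current:
        model_coords.append(current)

    if not atoms:
        raise EmptyStructureError("no atoms parsed from input")

    n = len(atoms)
    models = []
    for frame in model_coords:
        if len(frame) != n:
            raise PDBParseError(
                f"model with {len(frame)} atoms; expected {n} (shared topology)"
            )
        models.append(np.asarray(frame, dtype=float))
    return StructureModel(atoms=atoms, models=models, source_id=source_id)


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom_line(
    atom: Atom, xyz: Sequence[float], serial: int, occupancy: float | None = None
) -> str:
    rec = "HETATM" if atom.het else "ATOM  "
    name = atom.name
    # wwPDB: 1-3 char names start in column 14 unless 4 chars
    fname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    occ = atom.occupancy if occupancy is None else occupancy
    return (
        f"{rec}{serial:5d} {fname} {atom.resname:<3.3s} {atom.chain:1.1s}"
        f"{atom.resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element:>2.2s}"
    )


def write_pdb(structure: StructureModel, path: str | Path | None = None) -> str:
    """Serialize a structure to PDB text; write to *path* if given."""
    lines: list[str] = []
    multi = structure.n_models > 1
    for m, coords in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i, atom in enumerate(structure.atoms):
            lines.append(_format_atom_line(atom, coords[i], serial=i + 1))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_ensemble_pdb(
    path: str | Path,
    protein: StructureModel | None,
    labels: Iterable,
) -> str:
    """Write a protein plus attached label ensembles to one PDB file.

    Layout: the protein verbatim; then, per label, one MODEL block per
    rotamer with every atom's occupancy set to that rotamer's weight; then
    HETATM pseudo-atoms (name NEN, residue SCN) at each rotamer's spin
    center, occupancy again the rotamer weight.
    """
    lines: list[str] = []
    serial = 0
    if protein is not None:
        for i, atom in enumerate(protein.atoms):
            serial += 1
            lines.append(_format_atom_line(atom, protein.coords[i], serial))
        lines.append("TER")
    for label in labels:
        for r in range(label.n_rotamers):
            w = float(label.weights[r])
            lines.append(f"MODEL     {r + 1:4d}")
            for a in range(len(label.atom_names)):
                atom = Atom(
                    serial=0,
                    name=label.atom_names[a],
                    element=label.elements[a],
                    resname=label.resname,
                    resnum=label.site[1],
                    chain=label.site[0],
                    het=False,
                )
                serial += 1
                lines.append(
                    _format_atom_line(
                        atom, label.coords[r, a], serial, occupancy=w
                    )
                )
            lines.append("ENDMDL")
        centers = label.spin_centers
        for r in range(label.n_rotamers):
            pseudo = Atom(
                serial=0,
                name="NEN",
                element="N",
                resname="SCN",
                resnum=label.site[1],
                chain=label.site[0],
                het=True,
            )
            serial += 1
            lines.append(
                _format_atom_line(
                    pseudo, centers[r], serial, occupancy=float(label.weights[r])
                )
            )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Selection grammar

_KEYWORDS = {"chain", "resnum", "name", "element", "water", "and", "or", "not",
             "(", ")"}


def _tokenize(query: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(query):
        c = query[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(query) and not query[j].isspace() and query[j] not in "()":
            j += 1
        tokens.append((query[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser producing a boolean mask over atoms."""

    def __init__(self, tokens: list[tuple[str, int]], structure: StructureModel):
        self.tokens = tokens
        self.pos = 0
        self.s = structure

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, msg: str) -> None:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else -1
        raise QuerySyntaxError(f"{msg} (at position {at})")

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.pos != len(self.tokens):
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            self.fail("unexpected end of query")
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.peek() != ")":
                self.fail("missing ')'")
            self.take()
            return mask
        return self.primitive()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take()[0])
        if not vals:
            self.fail("expected one or more values")
        return vals

    def primitive(self) -> np.ndarray:
        tok, _ = self.take()
        atoms = self.s.atoms
        n = len(atoms)
        if tok == "water":
            return np.array([a.resname in WATER_RESNAMES for a in atoms])
        if tok == "chain":
            vals = set(self._values())
            return np.array([a.chain in vals for a in atoms])
        if tok == "name":
            vals = set(self._values())
            return np.array([a.name in vals for a in atoms])
        if tok == "element":
            vals = {v.capitalize() for v in self._values()}
            return np.array([a.element.capitalize() in vals for a in atoms])
        if tok == "resnum":
            mask = np.zeros(n, dtype=bool)
            for v in self._values():
                try:
                    if "-" in v and not v.startswith("-"):
                        lo, hi = (int(x) for x in v.split("-", 1))
                    else:
                        lo = hi = int(v)
                except ValueError:
                    self.pos -= 1
                    self.fail(f"bad resnum value {v!r}")
                mask |= np.array([lo <= a.resnum <= hi for a in atoms])
            return mask
        self.pos -= 1
        self.fail(f"unknown keyword {tok!r}")
        raise AssertionError  # unreachable


def select(structure: StructureModel, query: str) -> AtomSubset:
    """Select atoms with a small query grammar.

    Supported: ``chain <id...>``, ``resnum <n|n-m ...>``, ``name <list>``,
    ``element <list>``, ``water``, combined with ``and``/``or``/``not`` and
    parentheses. ``not water`` removes HOH/WAT residues.
    """
    tokens = _tokenize(query)
    if not tokens:
        raise QuerySyntaxError("empty query (at position 0)")
    mask = _Parser(tokens, structure).parse()
    return AtomSubset(structure, np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Mutation

def mutate(
    structure: StructureModel,
    chain: str,
    resnum: int,
    ensemble,
    rotamer_index: int,
) -> StructureModel:
    """Replace a residue's side chain with one rotamer of an attached ensemble.

    Backbone N, CA, C, O keep their input coordinates; everything else at the
    site is replaced by the rotamer's non-backbone atoms; the residue is
    renamed to the ensemble's residue name. Only the first model is mutated
    and returned.
    """
    if not (0 <= rotamer_index < ensemble.n_rotamers):
        raise IndexError(
            f"rotamer_index {rotamer_index} out of range "
            f"[0, {ensemble.n_rotamers})"
        )
    structure.backbone_indices(chain, resnum)  # raises if incomplete
    site_idx = set(structure.residue_indices(chain, resnum))

    new_atoms: list[Atom] = []
    new_coords: list[np.ndarray] = []
    inserted = False
    for i, atom in enumerate(structure.atoms):
        if i in site_idx:
            if atom.name in BACKBONE_NAMES:
                kept = copy.copy(atom)
                kept.resname = ensemble.resname
                new_atoms.append(kept)
                new_coords.append(structure.coords[i])
            if not inserted and atom.name == "C":
                # splice rotamer side chain right after the backbone C
                for a, aname in enumerate(ensemble.atom_names):
                    if aname in BACKBONE_NAMES:
                        continue
                    new_atoms.append(
                        Atom(
                            serial=0,
                            name=aname,
                            element=ensemble.elements[a],
                            resname=ensemble.resname,
                            resnum=resnum,
                            chain=chain,
                        )
                    )
                    new_coords.append(ensemble.coords[rotamer_index, a])
                inserted = True
        else:
            new_atoms.append(copy.copy(atom))
            new_coords.append(structure.coords[i])
    for i, a in enumerate(new_atoms):
        a.serial = i + 1
    return StructureModel(
        atoms=new_atoms,
        models=[np.asarray(new_coords, dtype=float)],
        source_id=structure.source_id,
    )
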