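"""Create, validate, save and load rotamer-library archives.

Archive format (``.rotlib.zip``): a ZIP container holding ``manifest.json``
plus one raw little-endian float64 file per array (``coords.f64``,
``weights.f64``, ``dihedrals.f64``), row-major, shapes and SHA-256
checksums recorded in the manifest. The container is deliberately
language-agnostic so libraries can be shared across tools.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from pathlib import Path

import numpy as np

from . import energetics
from .errors import (
    ArchiveVersionError,
    CorruptArchiveError,
    LibraryInvalidError,
    ModelInconsistencyError,
)
from .rotamer_core import (
    RotamerLibrary,
    bond_graph,
    measure_dihedral,
    to_canonical_frame,
)
from .structure_io import StructureModel

FORMAT_VERSION = "1.0"
ARRAY_FILES = ("coords.f64", "weights.f64", "dihedrals.f64")

__all__ = [
    "create_library",
    "save_library",
    "load_library",
    "validate_library",
    "FORMAT_VERSION",
]


def create_library(
    name: str,
    multistate_structure: StructureModel,
    dihedral_defs,
    spin_atoms,
    spin_weights,
    weights=None,
    dihedral_sigmas=None,
    energies=None,
    kT: float = energetics.DEFAULT_KT,
    resname: str | None = None,
) -> RotamerLibrary:
    """Build a rotamer library from a multistate conformer structure.

    Each model becomes one rotamer; coordinates are re-expressed in the
    canonical local frame per model, so any stereoisomeric heterogeneity
    among the models is preserved verbatim. Weights come from the *weights*
    argument (normalized), from *energies* via a Boltzmann factor at *kT*,
    or default to uniform; at most one of the two may be given. Single-model
    input and an empty ``dihedral_defs`` are both allowed.
    """
    if weights is not None and energies is not None:
        raise ValueError("provide at most one of weights and energies")
    s = multistate_structure
    if s.n_models < 1:
        raise ModelInconsistencyError("structure has no coordinate models")

    atom_names = [a.name for a in s.atoms]
    elements = [a.element for a in s.atoms]
    if len(set(atom_names)) != len(atom_names):
        raise ModelInconsistencyError("duplicate atom names in conformer input")
    for req in ("N", "CA", "C"):
        if req not in atom_names:
            raise LibraryInvalidError(f"conformers lack backbone atom {req}")
    iN, iCA, iC = (atom_names.index(n) for n in ("N", "CA", "C"))

    defs = [tuple(q) for q in dihedral_defs]
    for quad in defs:
        if len(quad) != 4:
            raise LibraryInvalidError(f"dihedral quadruplet {quad} must have 4 names")
        for n in quad:
            if n not in atom_names:
                raise LibraryInvalidError(f"dihedral atom {n!r} not in conformers")
    for n in spin_atoms:
        if n not in atom_names:
            raise LibraryInvalidError(f"spin atom {n!r} not in conformers")

    n_models = s.n_models
    coords = np.stack(
        [to_canonical_frame(m, iN, iCA, iC) for m in s.models]
    )
    quad_idx = [[atom_names.index(n) for n in q] for q in defs]
    dihedrals = np.array(
        [
            [
                measure_dihedral(*(m[i] for i in quad))
                for quad in quad_idx
            ]
            for m in coords
        ]
    ).reshape(n_models, len(defs))

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_models,):
            raise ValueError(f"weights must have shape ({n_models},)")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    elif energies is not None:
        e = np.asarray(energies, dtype=float)
        if e.shape != (n_models,):
            raise ValueError(f"energies must have shape ({n_models},)")
        w = energetics.reweight(np.full(n_models, 1.0 / n_models), e, kT)
    else:
        w = np.full(n_models, 1.0 / n_models)

    sw = np.asarray(spin_weights, dtype=float)
    if len(spin_atoms) != len(sw):
        raise ValueError("spin_atoms and spin_weights must have equal length")
    if len(sw):
        sw = sw / sw.sum()

    resname = resname or (s.atoms[iCA].resname if s.atoms else name)
    lib = RotamerLibrary(
        name=name,
        resname=resname,
        atom_names=atom_names,
        elements=elements,
        coords=coords,
        dihedral_defs=defs,
        dihedrals=dihedrals,
        weights=w,
        spin_atoms=list(spin_atoms),
        spin_weights=sw,
        dihedral_sigmas=(
            np.asarray(dihedral_sigmas, dtype=float)
            if dihedral_sigmas is not None
            else None
        ),
        format_version=FORMAT_VERSION,
    )
    failures = validate_library(lib)
    if failures:
        raise LibraryInvalidError("; ".join(failures))
    return lib


# ---------------------------------------------------------------------------
# Archive I/O

def _checksum(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def save_library(lib: RotamerLibrary, path: str | Path) -> Path:
    """Write a library to a ``.rotlib.zip`` archive."""
    path = Path(path)
    arrays = {
        "coords.f64": np.ascontiguousarray(lib.coords, dtype="<f8"),
        "weights.f64": np.ascontiguousarray(lib.weights, dtype="<f8"),
        "dihedrals.f64": np.ascontiguousarray(lib.dihedrals, dtype="<f8"),
    }
    manifest = {
        "format_version": lib.format_version,
        "name": lib.name,
        "resname": lib.resname,
        "atom_names": lib.atom_names,
        "elements": lib.elements,
        "dihedral_defs": [list(q) for q in lib.dihedral_defs],
        "spin_atoms": lib.spin_atoms,
        "spin_weights": lib.spin_weights.tolist(),
        "dihedral_sigmas": (
            lib.dihedral_sigmas.tolist() if lib.dihedral_sigmas is not None else None
        ),
        "downstream": [d.tolist() for d in lib.downstream],
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
        "checksums": {k: _checksum(v.tobytes()) for k, v in arrays.items()},
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for fname, arr in arrays.items():
            zf.writestr(fname, arr.tobytes())
    return path


def load_library(path: str | Path) -> RotamerLibrary:
    """Load a ``.rotlib.zip`` archive, verifying checksums and version."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        version = manifest.get("format_version")
        if version != FORMAT_VERSION:
            raise ArchiveVersionError(
                f"unsupported rotlib format version {version!r} "
                f"(expected {FORMAT_VERSION})"
            )
        arrays = {}
        for fname in ARRAY_FILES:
            raw = zf.read(fname)
            if _checksum(raw) != manifest["checksums"][fname]:
                raise CorruptArchiveError(f"checksum mismatch for {fname}")
            shape = tuple(manifest["shapes"][fname])
            arrays[fname] = np.frombuffer(raw, dtype="<f8").reshape(shape).copy()
    sig = manifest.get("dihedral_sigmas")
    lib = RotamerLibrary(
        name=manifest["name"],
        resname=manifest["resname"],
        atom_names=list(manifest["atom_names"]),
        elements=list(manifest["elements"]),
        coords=arrays["coords.f64"],
        dihedral_defs=[tuple(q) for q in manifest["dihedral_defs"]],
        dihedrals=arrays["dihedrals.f64"],
        weights=arrays["weights.f64"],
        spin_atoms=list(manifest["spin_atoms"]),
        spin_weights=np.asarray(manifest["spin_weights"], dtype=float),
        dihedral_sigmas=np.asarray(sig, dtype=float) if sig is not None else None,
        format_version=version,
    )
    ds = manifest.get("downstream")
    if ds is not None:
        lib._downstream = [np.asarray(d, dtype=np.intp) for d in ds]
    return lib


# ---------------------------------------------------------------------------
# Validation

def validate_library(lib: RotamerLibrary) -> list[str]:
    """Check all library invariants; returns a list of failure messages
    (empty if the library is valid)."""
    failures: list[str] = []
    R, A = lib.coords.shape[:2]
    if lib.coords.ndim != 3 or lib.coords.shape[2] != 3:
        failures.append(f"coords shape {lib.coords.shape} is not (R, A, 3)")
    if len(lib.atom_names) != A or len(lib.elements) != A:
        failures.append("atom_names/elements length does not match coords")
    if lib.weights.shape != (R,):
        failures.append(f"weights shape {lib.weights.shape} != ({R},)")
    elif np.any(lib.weights < 0) or abs(lib.weights.sum() - 1.0) > 1e-9:
        failures.append(
            f"weights must be >= 0 and sum to 1 (sum = {lib.weights.sum():.6f})"
        )
    k = lib.n_dihedrals
    if lib.dihedrals.shape != (R, k):
        failures.append(f"dihedrals shape {lib.dihedrals.shape} != ({R}, {k})")
    elif k and (
        not np.all(np.isfinite(lib.dihedrals))
        or np.any(lib.dihedrals <= -180.0)
        or np.any(lib.dihedrals > 180.0)
    ):
        failures.append("dihedrals must be finite and in (-180, 180]")
    if not np.all(np.isfinite(lib.coords)):
        failures.append("coords contain NaN/inf")
    if lib.dihedral_sigmas is not None and lib.dihedral_sigmas.shape not in (
        (k,),
        (R, k),
    ):
        failures.append(
            f"dihedral_sigmas shape {lib.dihedral_sigmas.shape} must be "
            f"({k},) or ({R}, {k})"
        )
    names = set(lib.atom_names)
    for quad in lib.dihedral_defs:
        for n in quad:
            if n not in names:
                failures.append(f"dihedral quadruplet names unknown atom {n!r}")
    for n in lib.spin_atoms:
        if n not in names:
            failures.append(f"spin atom {n!r} not among atom names")
    if lib.spin_atoms:
        if len(lib.spin_weights) != len(lib.spin_atoms):
            failures.append("spin_weights length != spin_atoms length")
        elif np.any(lib.spin_weights < 0) or abs(lib.spin_weights.sum() - 1.0) > 1e-9:
            failures.append("spin_weights must be >= 0 and sum to 1")
    # connectivity of mobile-dihedral quadruplets in the inferred bond graph
    if not failures:
        adj = bond_graph(lib.coords[0], lib.elements)
        for quad, idx in zip(lib.dihedral_defs, lib.dihedral_indices):
            for u, v in zip(idx[:-1], idx[1:]):
                if v not in adj[u]:
                    failures.append(
                        f"dihedral {quad}: atoms {lib.atom_names[u]} and "
                        f"{lib.atom_names[v]} are not bonded (<=1.9 Å rule)"
                    )
    return failures
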