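"""Rotamer-library data model, dihedral geometry, backbone superposition and
label attachment.

Conventions
-----------
* Dihedral angles are signed torsions in degrees, wrapped to (-180, 180],
  IUPAC sign convention.
* Every rotamer library lives in a canonical local frame: CA at the origin,
  the unit bisector of the N-CA-C angle along +x, the N-CA-C plane normal
  along +z. Attachment is then a pure frame-to-frame rigid map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from . import energetics
from .errors import (
    DegenerateGeometryError,
    DegenerateWeightsError,
    EmptyEnsembleError,
    LibraryInvalidError,
    UnknownDihedralError,
)
from .structure_io import BACKBONE_NAMES, AtomSubset, StructureModel, select

DEFAULT_SAMPLING_SIGMA = 35.0  # deg, used when a library provides no sigmas

__all__ = [
    "RigidTransform",
    "RotamerLibrary",
    "RotamerEnsemble",
    "SpinLabel",
    "measure_dihedral",
    "set_dihedral",
    "backbone_frame",
    "bisect_superposition",
    "triad_superposition",
    "to_canonical_frame",
    "bond_graph",
    "downstream_atoms",
    "build_coords_from_internal",
    "sample_off_rotamers",
    "attach",
]


# ---------------------------------------------------------------------------
# Elementary geometry

def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-8:
            raise DegenerateGeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise DegenerateGeometryError("collinear triple in dihedral")
    b2_hat = b2 / np.linalg.norm(b2)
    ang = np.degrees(
        np.arctan2(np.dot(np.cross(n1, n2), b2_hat), np.dot(n1, n2))
    )
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def wrap_angle(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    out = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(out) if out.ndim == 0 else out


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = _unit(axis, "rotation axis")
    th = np.radians(angle_deg)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def set_dihedral(
    coords: np.ndarray,
    quadruplet: Sequence[int],
    downstream: Sequence[int],
    value: float,
) -> np.ndarray:
    """Return coords with the torsion over *quadruplet* set to *value* (deg).

    Atoms listed in *downstream* rotate rigidly about the p2-p3 axis; all
    other atoms are untouched. Bond lengths and angles are preserved by
    construction.
    """
    coords = np.array(coords, dtype=float)
    i1, i2, i3, i4 = quadruplet
    current = measure_dihedral(coords[i1], coords[i2], coords[i3], coords[i4])
    delta = wrap_angle(value - current)
    axis = coords[i3] - coords[i2]
    R = _rotation_about_axis(axis, delta)
    ds = np.asarray(downstream, dtype=np.intp)
    coords[ds] = (coords[ds] - coords[i3]) @ R.T + coords[i3]
    return coords


# ---------------------------------------------------------------------------
# Rigid transforms and backbone superposition

@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise DegenerateGeometryError("rotation not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise DegenerateGeometryError("rotation not proper (det != +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def backbone_frame(N, CA, C) -> RigidTransform:
    """Orthonormal frame of a backbone triad (local -> global map).

    x = unit N-CA-C bisector, z = unit plane normal (N-arm cross C-arm),
    y = z cross x; origin at CA.
    """
    N, CA, C = (np.asarray(p, dtype=float) for p in (N, CA, C))
    n = _unit(N - CA, "CA->N")
    c = _unit(C - CA, "CA->C")
    cross = np.cross(n, c)
    if np.linalg.norm(cross) < 1e-8:
        raise DegenerateGeometryError("degenerate N-CA-C triad (collinear)")
    x = _unit(n + c, "bisector")
    z = _unit(cross, "plane normal")
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform(R, CA)


def bisect_superposition(
    src_N, src_CA, src_C, dst_N, dst_CA, dst_C
) -> RigidTransform:
    """Rigid map taking the source triad frame onto the destination frame.

    CA maps exactly onto CA; the N-CA-C bisector and plane normal of the
    source map onto those of the destination. When the two triads have
    different N-CA-C angles the N and C arms split the discrepancy
    symmetrically about the bisector.
    """
    fs = backbone_frame(src_N, src_CA, src_C)
    fd = backbone_frame(dst_N, dst_CA, dst_C)
    R = fd.rotation @ fs.rotation.T
    t = fd.translation - R @ fs.translation
    return RigidTransform(R, t)


def triad_superposition(src_triad, dst_triad) -> RigidTransform:
    """Least-squares (Kabsch) superposition of two 3-point triads."""
    src = np.asarray(src_triad, dtype=float)
    dst = np.asarray(dst_triad, dtype=float)
    # degenerate-triad guard, same criterion as the bisect method
    backbone_frame(*src)
    backbone_frame(*dst)
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def to_canonical_frame(
    coords: np.ndarray, iN: int, iCA: int, iC: int
) -> np.ndarray:
    """Re-express coordinates in the canonical local frame of their triad."""
    f = backbone_frame(coords[iN], coords[iCA], coords[iC])
    return f.inverse().apply(coords)


# ---------------------------------------------------------------------------
# Bond graph and internal coordinates

def bond_graph(
    coords: np.ndarray, elements: Sequence[str]
) -> list[set[int]]:
    """Adjacency inferred geometrically: <=1.9 Å heavy-heavy, <=1.2 Å to H,
    <=2.2 Å for S-S (disulfide bonds run ~2.05 Å)."""
    n = len(elements)
    adj: list[set[int]] = [set() for _ in range(n)]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    is_h = np.array([e.upper() == "H" for e in elements])
    is_s = np.array([e.upper() == "S" for e in elements])
    for i in range(n):
        for j in range(i + 1, n):
            if is_h[i] or is_h[j]:
                cut = 1.2
            elif is_s[i] and is_s[j]:
                cut = 2.2
            else:
                cut = 1.9
            if d[i, j] <= cut:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def downstream_atoms(
    adj: list[set[int]], i2: int, i3: int
) -> np.ndarray:
    """Atoms that rotate with the i2-i3 bond: the i3-side component, minus i3.

    The edge i2-i3 is removed and everything reachable from i3 (excluding i3
    itself, which sits on the axis) is returned, sorted.
    """
    seen = {i3, i2}
    stack = [j for j in adj[i3] if j != i2]
    out = []
    while stack:
        k = stack.pop()
        if k in seen:
            continue
        seen.add(k)
        out.append(k)
        stack.extend(adj[k] - seen)
    return np.array(sorted(out), dtype=np.intp)


class ZMatrixRow(NamedTuple):
    atom: int
    refs: tuple[int, int, int]  # bonded, angle, torsion references
    bond: float
    angle: float  # deg
    torsion: float  # deg


def _place_atom(c, b, a, bond, angle_deg, torsion_deg) -> np.ndarray:
    """NeRF placement: new atom x with |x-c| = bond, angle(x,c,b) = angle,
    dihedral(a,b,c,x) = torsion."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = _unit(c - b, "z-matrix bc")
    n = _unit(np.cross(b - a, bc), "z-matrix plane")
    m = np.cross(n, bc)
    local = bond * np.array(
        [
            -np.cos(theta),
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
        ]
    )
    return c + np.column_stack([bc, m, n]) @ local


def derive_zmatrix(
    coords: np.ndarray,
    adj: list[set[int]],
    iN: int,
    iCA: int,
    iC: int,
) -> list[ZMatrixRow]:
    """Internal-coordinate table from Cartesian coords and a bond graph.

    Placement starts from the N/CA/C triad; each further atom is defined by
    (bonded parent, grandparent, great-grandparent) along a BFS tree. Raises
    LibraryInvalidError if any atom is unreachable from the backbone.
    """
    n = len(coords)
    parent: dict[int, int] = {iCA: -1, iN: iCA, iC: iCA}
    placed = [iN, iCA, iC]
    placed_set = set(placed)
    rows: list[ZMatrixRow] = []
    queue = [iN, iCA, iC]
    while queue:
        p = queue.pop(0)
        for a in sorted(adj[p]):
            if a in placed_set:
                continue
            if p == iCA:
                refs = (iCA, iN, iC)
            elif p == iN:
                refs = (iN, iCA, iC)
            elif p == iC:
                refs = (iC, iCA, iN)
            else:
                g = parent[p]
                gg = parent[g]
                if gg < 0:  # g == CA
                    gg = iN if p != iN else iC
                refs = (p, g, gg)
            r1, r2, r3 = refs
            rows.append(
                ZMatrixRow(
                    atom=a,
                    refs=refs,
                    bond=float(np.linalg.norm(coords[a] - coords[r1])),
                    angle=_angle(coords[a], coords[r1], coords[r2]),
                    torsion=measure_dihedral(
                        coords[r3], coords[r2], coords[r1], coords[a]
                    ),
                )
            )
            parent[a] = p
            placed.append(a)
            placed_set.add(a)
            queue.append(a)
    if len(placed) != n:
        missing = sorted(set(range(n)) - placed_set)
        raise LibraryInvalidError(
            f"internal-coordinate table incomplete: atoms {missing} "
            "not bonded to the backbone"
        )
    return rows


def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = _unit(np.asarray(a, float) - b, "angle arm")
    v = _unit(np.asarray(c, float) - b, "angle arm")
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Rotamer library

@dataclass
class RotamerLibrary:
    """A portable side-chain template ensemble.

    Coordinates are stored per rotamer in the canonical local frame; the
    internal-coordinate table is derived on demand from the first rotamer
    and the geometric bond graph.
    """

    name: str
    resname: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (R, A, 3) canonical frame
    dihedral_defs: list[tuple[str, str, str, str]]
    dihedrals: np.ndarray  # (R, K)
    weights: np.ndarray  # (R,)
    spin_atoms: list[str] = field(default_factory=list)
    spin_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedral_sigmas: np.ndarray | None = None  # (K,) or (R, K)
    format_version: str = "1.0"
    _adj: list[set[int]] | None = field(default=None, repr=False)
    _downstream: list[np.ndarray] | None = field(default=None, repr=False)
    _zmatrix: list[ZMatrixRow] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.spin_weights = np.asarray(self.spin_weights, dtype=float)
        if self.dihedral_sigmas is not None:
            self.dihedral_sigmas = np.asarray(self.dihedral_sigmas, dtype=float)

    # -- topology helpers ---------------------------------------------------

    @property
    def n_rotamers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return len(self.dihedral_defs)

    def atom_index(self, name: str) -> int:
        try:
            return self.atom_names.index(name)
        except ValueError as exc:
            raise LibraryInvalidError(
                f"atom {name!r} not in library {self.name!r}"
            ) from exc

    @property
    def backbone_triad(self) -> tuple[int, int, int]:
        return (self.atom_index("N"), self.atom_index("CA"), self.atom_index("C"))

    @property
    def side_chain_mask(self) -> np.ndarray:
        return np.array(
            [n not in BACKBONE_NAMES for n in self.atom_names], dtype=bool
        )

    @property
    def dihedral_indices(self) -> np.ndarray:
        return np.array(
            [[self.atom_index(n) for n in quad] for quad in self.dihedral_defs],
            dtype=np.intp,
        ).reshape(-1, 4)

    @property
    def adjacency(self) -> list[set[int]]:
        if self._adj is None:
            self._adj = bond_graph(self.coords[0], self.elements)
        return self._adj

    @property
    def downstream(self) -> list[np.ndarray]:
        if self._downstream is None:
            self._downstream = [
                downstream_atoms(self.adjacency, q[1], q[2])
                for q in self.dihedral_indices
            ]
        return self._downstream

    @property
    def zmatrix(self) -> list[ZMatrixRow]:
        if self._zmatrix is None:
            iN, iCA, iC = self.backbone_triad
            self._zmatrix = derive_zmatrix(
                self.coords[0], self.adjacency, iN, iCA, iC
            )
        return self._zmatrix

    def resolve_sigmas(self, override=None) -> np.ndarray:
        """Per-rotamer x per-dihedral sampling widths (deg)."""
        k = self.n_dihedrals
        sig = override if override is not None else self.dihedral_sigmas
        if sig is None:
            sig = DEFAULT_SAMPLING_SIGMA
        sig = np.asarray(sig, dtype=float)
        return np.broadcast_to(sig, (self.n_rotamers, k)).copy()

    def coords_for_dihedrals(
        self, parent: int, dihedral_values: np.ndarray
    ) -> np.ndarray:
        """Coordinates of rotamer *parent* with its mobile dihedrals set to
        the given values (preserves any stereoisomeric detail)."""
        coords = self.coords[parent]
        for quad, ds, val in zip(
            self.dihedral_indices, self.downstream, dihedral_values
        ):
            coords = set_dihedral(coords, quad, ds, val)
        return coords


def build_coords_from_internal(
    library: RotamerLibrary, dihedral_values: Sequence[float]
) -> np.ndarray:
    """Cartesian coordinates (canonical frame) from the library's internal
    coordinates with mobile dihedrals set to *dihedral_values*."""
    vals = np.asarray(dihedral_values, dtype=float)
    if vals.shape != (library.n_dihedrals,):
        raise UnknownDihedralError(
            f"expected {library.n_dihedrals} dihedral values, got {vals.shape}"
        )
    iN, iCA, iC = library.backbone_triad
    n = len(library.atom_names)
    coords = np.zeros((n, 3))
    template = library.coords[0]
    coords[iN] = template[iN]
    coords[iCA] = template[iCA]
    coords[iC] = template[iC]
    for row in library.zmatrix:
        r1, r2, r3 = row.refs
        coords[row.atom] = _place_atom(
            coords[r1], coords[r2], coords[r3], row.bond, row.angle, row.torsion
        )
    for quad, ds, val in zip(library.dihedral_indices, library.downstream, vals):
        coords = set_dihedral(coords, quad, ds, val)
    return coords


# ---------------------------------------------------------------------------
# Ensembles

@dataclass
class RotamerEnsemble:
    """A rotamer library instantiated at a protein site."""

    library: RotamerLibrary
    site: tuple[str, int]
    coords: np.ndarray  # (R, A, 3) protein frame
    weights: np.ndarray  # (R,), sum 1
    dihedrals: np.ndarray  # (R, K)
    provenance: dict = field(default_factory=dict)

    @property
    def n_rotamers(self) -> int:
        return self.coords.shape[0]

    @property
    def atom_names(self) -> list[str]:
        return self.library.atom_names

    @property
    def elements(self) -> list[str]:
        return self.library.elements

    @property
    def resname(self) -> str:
        return self.library.resname

    @property
    def side_chain_mask(self) -> np.ndarray:
        return self.library.side_chain_mask

    @property
    def side_chain_coords(self) -> np.ndarray:
        return self.coords[:, self.side_chain_mask, :]

    @property
    def side_chain_elements(self) -> list[str]:
        return [e for e, m in zip(self.elements, self.side_chain_mask) if m]

    @property
    def clash_mask(self) -> np.ndarray:
        """Atoms scored against the environment: side chain beyond CB.

        CB is positioned by the backbone alignment (identical across
        rotamers) and sits 1-3/1-4 to neighboring backbone atoms, so it is
        excluded from clash evaluation like the backbone itself.
        """
        return np.array(
            [
                n not in BACKBONE_NAMES and n != "CB"
                for n in self.atom_names
            ],
            dtype=bool,
        )

    @property
    def clash_coords(self) -> np.ndarray:
        return self.coords[:, self.clash_mask, :]

    @property
    def clash_elements(self) -> list[str]:
        return [e for e, m in zip(self.elements, self.clash_mask) if m]

    @property
    def centroid(self) -> np.ndarray:
        """Weight-averaged heavy-atom centroid of the whole ensemble."""
        heavy = np.array([e.upper() != "H" for e in self.elements])
        per_rot = self.coords[:, heavy, :].mean(axis=1)
        return np.einsum("r,rx->x", self.weights, per_rot)


@dataclass
class SpinLabel(RotamerEnsemble):
    """A rotamer ensemble carrying a spin-density distribution."""

    spin_atoms: list[str] = field(default_factory=list)
    spin_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def spin_atom_indices(self) -> np.ndarray:
        return np.array(
            [self.library.atom_index(n) for n in self.spin_atoms], dtype=np.intp
        )

    @property
    def spin_coords(self) -> np.ndarray:
        """(R, n_spin_atoms, 3) coordinates of the spin-bearing atoms."""
        return self.coords[:, self.spin_atom_indices, :]

    @property
    def spin_centers(self) -> np.ndarray:
        """(R, 3): per-rotamer spin-weight-averaged spin-atom position."""
        return np.einsum("s,rsx->rx", self.spin_weights, self.spin_coords)

    @property
    def spin_centroid(self) -> np.ndarray:
        """Ensemble-weight-averaged spin center."""
        return np.einsum("r,rx->x", self.weights, self.spin_centers)


# ---------------------------------------------------------------------------
# Off-rotamer sampling

class OffRotamerSample(NamedTuple):
    dihedrals: np.ndarray  # (n, K)
    weights: np.ndarray  # (n,)
    parents: np.ndarray  # (n,)


def sample_off_rotamers(
    library: RotamerLibrary,
    n: int,
    dihedral_sigmas=None,
    rng: np.random.Generator | int | None = None,
) -> OffRotamerSample:
    """Draw *n* off-rotamer dihedral sets.

    Each sample picks a parent rotamer with probability equal to its library
    weight, then perturbs every mobile dihedral by a wrapped normal of the
    per-dihedral sigma; sigma = inf means uniform on (-180, 180] (the
    accessible-volume limit). Sample weights are uniform 1/n.
    """
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    sig = library.resolve_sigmas(dihedral_sigmas)
    if np.any(sig[np.isfinite(sig)] < 0):
        raise ValueError("dihedral_sigmas must be >= 0")
    parents = rng.choice(library.n_rotamers, size=n, p=library.weights)
    k = library.n_dihedrals
    dihedrals = np.empty((n, k))
    for i, p in enumerate(parents):
        for j in range(k):
            s = sig[p, j]
            if np.isinf(s):
                dihedrals[i, j] = wrap_angle(rng.uniform(-180.0, 180.0))
            elif s == 0.0:
                dihedrals[i, j] = library.dihedrals[p, j]
            else:
                dihedrals[i, j] = wrap_angle(
                    library.dihedrals[p, j] + rng.normal(0.0, s)
                )
    return OffRotamerSample(dihedrals, np.full(n, 1.0 / n), parents)


# ---------------------------------------------------------------------------
# Attachment

def attach(
    library: RotamerLibrary,
    protein: StructureModel,
    chain: str,
    resnum: int,
    *,
    sample: int | None = None,
    dihedral_sigmas=None,
    alignment: str = "bisect",
    eval_clash: bool = True,
    energy_func: Callable | None = None,
    params: energetics.LJParams | None = None,
    kT: float = energetics.DEFAULT_KT,
    trim_tol: float = energetics.DEFAULT_TRIM_TOL,
    environment: AtomSubset | None = None,
    rng_seed=None,
) -> SpinLabel | RotamerEnsemble:
    """Attach a rotamer library to a protein site, returning a SpinLabel
    (or plain RotamerEnsemble if the library has no spin atoms).

    With ``sample=None`` the library rotamers are aligned as-is (rotamer
    library method); with ``sample=n``, n off-rotamer samples are generated
    instead; ``dihedral_sigmas=np.inf`` with sampling gives the
    accessible-volume method. With ``eval_clash``, rotamer energies against
    the surrounding structure (waters and the site's own side chain
    excluded) reweight and trim the ensemble.
    """
    iN, iCA, iC = protein.backbone_indices(chain, resnum)
    pc = protein.coords
    liN, liCA, liC = library.backbone_triad

    if sample is None:
        local = library.coords
        dihedrals = library.dihedrals.copy()
        prior = library.weights.copy()
        method = "rotlib"
        parents = np.arange(library.n_rotamers)
    else:
        draw = sample_off_rotamers(
            library, sample, dihedral_sigmas=dihedral_sigmas, rng=rng_seed
        )
        local = np.stack(
            [
                library.coords_for_dihedrals(p, d)
                for p, d in zip(draw.parents, draw.dihedrals)
            ]
        )
        dihedrals = draw.dihedrals
        prior = draw.weights
        method = "sample"
        parents = draw.parents

    placed = np.empty_like(local)
    for r in range(local.shape[0]):
        src = (local[r, liN], local[r, liCA], local[r, liC])
        if alignment == "bisect":
            tf = bisect_superposition(*src, pc[iN], pc[iCA], pc[iC])
        elif alignment == "triad":
            tf = triad_superposition(
                np.stack(src), np.stack([pc[iN], pc[iCA], pc[iC]])
            )
        else:
            raise ValueError(f"unknown alignment method {alignment!r}")
        placed[r] = tf.apply(local[r])

    provenance = {
        "method": method,
        "alignment": alignment,
        "sample": sample,
        "eval_clash": eval_clash,
        "rng_seed": rng_seed,
    }

    if library.spin_atoms:
        label: RotamerEnsemble = SpinLabel(
            library=library,
            site=(chain, resnum),
            coords=placed,
            weights=prior / prior.sum(),
            dihedrals=dihedrals,
            provenance=provenance,
            spin_atoms=list(library.spin_atoms),
            spin_weights=np.asarray(library.spin_weights, dtype=float),
        )
    else:
        label = RotamerEnsemble(
            library=library,
            site=(chain, resnum),
            coords=placed,
            weights=prior / prior.sum(),
            dihedrals=dihedrals,
            provenance=provenance,
        )

    if eval_clash:
        env = _clash_environment(protein, chain, resnum, environment)
        params = params or energetics.LJParams()
        func = energy_func or energetics.flat_top_repulsive_lj
        energies = np.asarray(func(label, env, params), dtype=float)
        # if even the best rotamer carries a fully capped clash, the site is
        # considered unlabelable rather than silently keeping one survivor
        if energies.size and float(np.min(energies)) >= params.cap:
            raise EmptyEnsembleError(
                f"every rotamer clashes at site {chain}/{resnum} "
                f"(min energy {energies.min():.2f} >= cap {params.cap}); "
                "consider a smaller forgive factor or a larger cap"
            )
        try:
            posterior = energetics.reweight(label.weights, energies, kT)
        except DegenerateWeightsError as exc:
            raise EmptyEnsembleError(
                f"all rotamers clash at site {chain}/{resnum}; consider a "
                "smaller forgive factor's complement (larger forgive) or "
                "a larger energy cap"
            ) from exc
        label.weights = posterior
        keep = energetics.trim_indices(posterior, trim_tol)
        label.coords = label.coords[keep]
        label.weights = posterior[keep] / posterior[keep].sum()
        label.dihedrals = label.dihedrals[keep]
        provenance.update(
            {
                "forgive": params.forgive,
                "cap": params.cap,
                "clash_radius": params.cutoff,
                "kT": kT,
                "trim_tol": trim_tol,
            }
        )
    return label


def _clash_environment(
    protein: StructureModel,
    chain: str,
    resnum: int,
    environment: AtomSubset | None,
) -> AtomSubset:
    """Environment subset for clash scoring: the provided subset (or all
    atoms) minus waters and minus the labeled residue (whose backbone is
    bonded to, and whose side chain is replaced by, the label)."""
    if environment is None:
        idx = np.arange(protein.n_atoms)
    else:
        if environment.structure is not protein:
            raise ValueError("environment subset must reference the protein")
        idx = environment.indices
    keep = []
    for i in idx:
        a = protein.atoms[i]
        if a.resname in ("HOH", "WAT"):
            continue
        if a.chain == chain and a.resnum == resnum:
            continue
        keep.append(i)
    return AtomSubset(protein, np.asarray(keep, dtype=np.intp))
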