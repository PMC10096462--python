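"""Synthetic test inputs: ideal helices, a toy nitroxide-like label library,
a two-state hinge protein, and synthetic membrane-depth datasets.

These fixtures validate code paths, not chemistry; geometries are idealized
but dimensioned so that spin centers sit 4-8 Å from CA, comparable to real
nitroxide labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import library_builder, rotamer_core
from .docking import DepthDataset, DepthRecord, DockingPose, pose_transform
from .rotamer_core import RotamerLibrary, _place_atom, _rotation_about_axis
from .structure_io import Atom, StructureModel

# standard backbone geometry (Å, deg)
_B = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "CA-CB": 1.521,
    "N-CA-C": 111.0,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "N-CA-CB": 110.5,
    "CB-improper": -122.6,  # dihedral C-N-CA-CB, L-amino acid
}

__all__ = [
    "FixtureSpec",
    "make_helix",
    "make_toy_label_library",
    "make_hinge",
    "make_depths",
]


@dataclass
class FixtureSpec:
    kind: str  # helix | hinge | toy_label | depths
    parameters: dict
    rng_seed: int | None = None


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict]:
    """Backbone + O + CB coordinates for an ideal poly-ALA chain."""
    residues: list[dict] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.radians(_B["N-CA-C"])
    C = CA + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            prev = residues[-1]
            N = _place_atom(prev["C"], prev["CA"], prev["N"], _B["C-N"],
                            _B["CA-C-N"], psi)
            CA = _place_atom(N, prev["C"], prev["CA"], _B["N-CA"],
                             _B["C-N-CA"], 180.0)
            C = _place_atom(CA, N, prev["C"], _B["CA-C"], _B["N-CA-C"], phi)
        res = {"N": N, "CA": CA, "C": C}
        res["CB"] = _place_atom(CA, N, C, _B["CA-CB"], _B["N-CA-CB"],
                                _B["CB-improper"])
        residues.append(res)
    # carbonyl O needs the next residue's N (or psi continuation at the end)
    for i, res in enumerate(residues):
        res["O"] = _place_atom(res["C"], res["CA"], res["N"], _B["C-O"],
                               _B["CA-C-O"], psi + 180.0)
    return residues


def make_helix(n_res: int, chain: str = "A") -> StructureModel:
    """Ideal alpha-helical poly-alanine (phi = -57, psi = -47), helix axis
    aligned with +z, full backbone plus O and CB."""
    if n_res < 3:
        raise ValueError(f"helix needs >= 3 residues, got {n_res}")
    residues = _build_backbone(n_res, phi=-57.0, psi=-47.0)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for i, res in enumerate(residues, start=1):
        for name in ("N", "CA", "C", "O", "CB"):
            el = name[0]
            atoms.append(
                Atom(serial=len(atoms) + 1, name=name, element=el,
                     resname="ALA", resnum=i, chain=chain)
            )
            coords.append(res[name])
    xyz = np.asarray(coords)
    # rotate so the helix axis (first principal axis of the CA trace) is +z
    ca = xyz[1::5]
    centered = ca - ca.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    axis = Vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s > 1e-12:
        R = _rotation_about_axis(v, np.degrees(np.arctan2(s, np.dot(axis, z))))
        xyz = (xyz - ca.mean(axis=0)) @ R.T
    else:
        xyz = xyz - ca.mean(axis=0)
    return StructureModel(atoms=atoms, models=[xyz], source_id=f"helix{n_res}")


# ---------------------------------------------------------------------------
# Toy nitroxide-like label

_TOY_CHI = [(-60.0, 180.0), (180.0, 180.0), (60.0, -60.0)]
_TOY_WEIGHTS = (0.5, 0.3, 0.2)


def _toy_conformer(chi1: float, chi2: float) -> tuple[list[str], list[str], np.ndarray]:
    """One toy-label conformer: backbone + CB-SG-C1-N1-O1 arm."""
    res = _build_backbone(1, phi=-57.0, psi=-47.0)[0]
    SG = _place_atom(res["CB"], res["CA"], res["N"], 1.81, 114.0, chi1)
    C1 = _place_atom(SG, res["CB"], res["CA"], 1.80, 105.0, chi2)
    N1 = _place_atom(C1, SG, res["CB"], 1.40, 120.0, 180.0)
    O1 = _place_atom(N1, C1, SG, 1.30, 120.0, 180.0)
    names = ["N", "CA", "C", "O", "CB", "SG", "C1", "N1", "O1"]
    elements = ["N", "C", "C", "O", "C", "S", "C", "N", "O"]
    xyz = np.stack([res["N"], res["CA"], res["C"], res["O"], res["CB"],
                    SG, C1, N1, O1])
    return names, elements, xyz


def make_toy_label_library() -> RotamerLibrary:
    """3-rotamer nitroxide-like label: spin density split over N1/O1, two
    mobile dihedrals, weights (0.5, 0.3, 0.2)."""
    models = []
    for chi1, chi2 in _TOY_CHI:
        names, elements, xyz = _toy_conformer(chi1, chi2)
        models.append(xyz)
    atoms = [
        Atom(serial=i + 1, name=n, element=e, resname="TNX", resnum=1,
             chain="A")
        for i, (n, e) in enumerate(zip(names, elements))
    ]
    structure = StructureModel(atoms=atoms, models=models, source_id="toy_label")
    return library_builder.create_library(
        name="TOY",
        multistate_structure=structure,
        dihedral_defs=[("N", "CA", "CB", "SG"), ("CA", "CB", "SG", "C1")],
        spin_atoms=["N1", "O1"],
        spin_weights=[0.5, 0.5],
        weights=list(_TOY_WEIGHTS),
        resname="TNX",
    )


# ---------------------------------------------------------------------------
# R1-like nitroxide label (idealized geometry)

# chi grids: chi1/chi2 staggered (gauche-/trans preferred), chi3 disulfide
# +/-90, chi4 staggered-ish, chi5 ring orientation +/-90
_R1_CHI_GRID = (
    (-60.0, 180.0),
    (-60.0, 60.0, 180.0),
    (-90.0, 90.0),
    (-75.0, 75.0, 180.0),
    (-90.0, 90.0),
)

_R1_ZMAT = [
    # name, element, refs (bonded, angle, torsion), bond Å, angle deg,
    # torsion deg or chi index
    ("SG", "S", ("CB", "CA", "N"), 1.81, 114.0, "chi1"),
    ("SD", "S", ("SG", "CB", "CA"), 2.03, 104.0, "chi2"),
    ("CE", "C", ("SD", "SG", "CB"), 1.81, 104.0, "chi3"),
    ("C3", "C", ("CE", "SD", "SG"), 1.50, 110.0, "chi4"),
    ("C4", "C", ("C3", "CE", "SD"), 1.33, 126.0, "chi5"),
    ("C5", "C", ("C4", "C3", "CE"), 1.51, 112.0, 180.0),
    ("N1", "N", ("C5", "C4", "C3"), 1.47, 103.0, 0.0),
    ("C2", "C", ("N1", "C5", "C4"), 1.48, 112.0, 0.0),
    ("O1", "O", ("N1", "C5", "C4"), 1.28, 122.0, 180.0),
    ("C6", "C", ("C2", "N1", "C5"), 1.53, 110.0, 120.0),
    ("C7", "C", ("C2", "N1", "C5"), 1.53, 110.0, -120.0),
    ("C8", "C", ("C5", "C4", "C3"), 1.53, 111.0, 122.0),
    ("C9", "C", ("C5", "C4", "C3"), 1.53, 111.0, -118.0),
]

R1_DIHEDRAL_DEFS = [
    ("N", "CA", "CB", "SG"),
    ("CA", "CB", "SG", "SD"),
    ("CB", "SG", "SD", "CE"),
    ("SG", "SD", "CE", "C3"),
    ("SD", "CE", "C3", "C4"),
]


def _r1_conformer(chis) -> tuple[list[str], list[str], np.ndarray]:
    res = _build_backbone(1, phi=-57.0, psi=-47.0)[0]
    pos = {"N": res["N"], "CA": res["CA"], "C": res["C"], "O": res["O"],
           "CB": res["CB"]}
    chi_map = {f"chi{i + 1}": chis[i] for i in range(5)}
    names = ["N", "CA", "C", "O", "CB"]
    elements = ["N", "C", "C", "O", "C"]
    for name, el, (r1, r2, r3), bond, angle, torsion in _R1_ZMAT:
        t = chi_map.get(torsion, torsion)
        pos[name] = _place_atom(pos[r1], pos[r2], pos[r3], bond, angle, t)
        names.append(name)
        elements.append(el)
    return names, elements, np.stack([pos[n] for n in names])


def make_r1_like_library() -> RotamerLibrary:
    """Idealized MTSL-like nitroxide label: a CB-SG-SD-CE disulfide-linked
    tetramethyl-pyrroline ring, five mobile dihedrals on a staggered/known
    preference grid (72 uniform-weight rotamers), spin density split evenly
    over the ring N1/O1 atoms.

    The geometry is built from standard bond lengths/angles, not from a
    quantum-chemistry conformer set, so predictions carry library-provenance
    uncertainty of a few Å.
    """
    chis = [[]]
    for grid in _R1_CHI_GRID:
        chis = [c + [v] for c in chis for v in grid]
    models = []
    for c in chis:
        names, elements, xyz = _r1_conformer(c)
        models.append(xyz)
    atoms = [
        Atom(serial=i + 1, name=n, element=e, resname="R1X", resnum=1,
             chain="A")
        for i, (n, e) in enumerate(zip(names, elements))
    ]
    structure = StructureModel(atoms=atoms, models=models,
                               source_id="r1_like")
    return library_builder.create_library(
        name="R1-like",
        multistate_structure=structure,
        dihedral_defs=R1_DIHEDRAL_DEFS,
        spin_atoms=["N1", "O1"],
        spin_weights=[0.5, 0.5],
        resname="R1X",
    )


# ---------------------------------------------------------------------------
# Two-state hinge

def hinge_special_pair(n_res: int) -> tuple[tuple[str, int], tuple[str, int]]:
    """The constructed decoupled pair (arm-1 site, far arm-2 site): large
    CB-CB backbone change, spin-centroid distance invariant by axis choice."""
    return (("A", 2), ("A", n_res - 4))


def hinge_axis(n_res: int, hinge_angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic hinge axis (unit vector) and pivot point.

    The axis passes through the middle CA and its direction is chosen so
    that the spin centroid of the far special-pair site lands on the
    perpendicular bisector plane of its own motion as seen from the arm-1
    special site — i.e. the pair's spin-centroid distance is exactly
    unchanged by the hinge — while maximizing the pair's CB-CB distance
    change among all such directions. This decouples backbone change from
    spin-distance change by construction.
    """
    from scipy.optimize import brentq

    state_a = make_helix(n_res)
    mid = n_res // 2
    pivot = state_a.coords[state_a.atom_index("A", mid, "CA")]
    lib = make_toy_label_library()
    s1, s2 = hinge_special_pair(n_res)
    c1 = rotamer_core.attach(lib, state_a, *s1, eval_clash=False).spin_centroid
    c2 = rotamer_core.attach(lib, state_a, *s2, eval_clash=False).spin_centroid
    cb1 = state_a.coords[state_a.atom_index(*s1, "CB")]
    cb2 = state_a.coords[state_a.atom_index(*s2, "CB")]
    d0 = np.linalg.norm(c1 - c2)
    db0 = np.linalg.norm(cb1 - cb2)

    def unit(th, ph):
        return np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )

    def moved(axis, p):
        R = _rotation_about_axis(axis, hinge_angle)
        return R @ (p - pivot) + pivot

    def spin_mismatch(th, ph):
        return np.linalg.norm(c1 - moved(unit(th, ph), c2)) - d0

    best = None
    for ph in np.linspace(0.0, 2 * np.pi, 73)[:-1]:
        ths = np.linspace(1e-3, np.pi - 1e-3, 40)
        vals = [spin_mismatch(t, ph) for t in ths]
        for i in range(len(ths) - 1):
            if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                t0 = brentq(
                    lambda t: spin_mismatch(t, ph), ths[i], ths[i + 1]
                )
                axis = unit(t0, ph)
                change = abs(np.linalg.norm(cb1 - moved(axis, cb2)) - db0)
                if best is None or change > best[0]:
                    best = (change, axis)
    if best is None:  # no exact-invariance direction; fall back to bending
        best = (0.0, np.array([1.0, 0.0, 0.0]))
    return best[1], pivot


def make_hinge(
    n_res: int, hinge_angle: float
) -> tuple[StructureModel, StructureModel]:
    """Two-state hinge: a helix whose second arm rotates by *hinge_angle*
    about an axis through the middle CA (see ``hinge_axis``).

    By construction the ``hinge_special_pair`` sites keep their
    spin-centroid distance exactly while their CB-CB distance changes
    substantially (clearly so for angles >= 90 degrees); generic cross-arm
    pairs change their spin distances strongly.
    """
    if n_res < 8:
        raise ValueError(f"hinge needs >= 8 residues, got {n_res}")
    if not (0.0 <= hinge_angle < 180.0):
        raise ValueError("hinge_angle must be in [0, 180)")
    state_a = make_helix(n_res)
    mid = n_res // 2
    state_b = state_a.copy()
    if hinge_angle > 0:
        axis, pivot = hinge_axis(n_res, hinge_angle)
        R = _rotation_about_axis(axis, hinge_angle)
        moving = np.array(
            [a.resnum > mid for a in state_b.atoms], dtype=bool
        )
        xyz = state_b.models[0]
        xyz[moving] = (xyz[moving] - pivot) @ R.T + pivot
    state_b.source_id = f"hinge{n_res}B"
    state_a.source_id = f"hinge{n_res}A"
    return state_a, state_b


# ---------------------------------------------------------------------------
# Synthetic depth data

def make_depths(
    structure: StructureModel,
    sites: list[tuple[str, int]],
    true_pose: DockingPose,
    noise_sigma: float = 0.0,
    rng_seed=None,
    library: RotamerLibrary | None = None,
    eval_clash: bool = False,
) -> tuple[DepthDataset, dict]:
    """Depths = z of the transformed spin centroids under *true_pose*, plus
    optional Gaussian noise. Returns (dataset, spin_centroids dict)."""
    rng = np.random.default_rng(rng_seed)
    lib = library or make_toy_label_library()
    centroids = {}
    for chain, resnum in sites:
        label = rotamer_core.attach(
            lib, structure, chain, resnum, eval_clash=eval_clash
        )
        centroids[(chain, resnum)] = label.spin_centroid
    if true_pose.center is None:
        true_pose.center = np.mean(list(centroids.values()), axis=0)
    tf = pose_transform(true_pose)
    records = []
    for site in sites:
        z = tf.apply(centroids[site])[2]
        if noise_sigma > 0:
            z = z + rng.normal(0.0, noise_sigma)
        records.append(DepthRecord(chain=site[0], resnum=site[1],
                                   depth=float(z)))
    return DepthDataset(records), centroids
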