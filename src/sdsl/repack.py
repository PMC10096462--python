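"""Markov-chain Monte Carlo repacking of a spin label and its neighbors.

Each step picks one repack-region site uniformly at random, draws a rotamer
from that site's library by prior weight (optionally with off-rotamer
dihedral perturbation) and accepts or rejects on the energy change. Native
residues get their rotamer sets generated from their own observed side-chain
geometry with standard chi-angle conventions, so no external rotamer
database is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import energetics
from .errors import UnsupportedResidueError
from .rotamer_core import (
    RotamerEnsemble,
    RotamerLibrary,
    SpinLabel,
    attach,
    wrap_angle,
)
from .structure_io import (
    BACKBONE_NAMES,
    WATER_RESNAMES,
    Atom,
    AtomSubset,
    StructureModel,
)

DEFAULT_RADIUS = 10.0  # Å
DEFAULT_BURN_IN_FRACTION = 0.2

# standard mobile-dihedral (chi) quadruplets per side-chain-bearing residue
CHI_DEFS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}
_AROMATIC = {"PHE", "TYR", "TRP", "HIS"}
_FIXED_SIDE_CHAINS = {"GLY", "ALA", "PRO"}

__all__ = [
    "RepackTrajectory",
    "repack",
    "from_trajectory",
    "site_rotamer_library",
    "CHI_DEFS",
]


def site_rotamer_library(
    structure: StructureModel, chain: str, resnum: int
) -> RotamerLibrary:
    """Backbone-independent rotamer set for a native residue, derived from
    its own observed side-chain geometry with chi values on the standard
    staggered grid (aromatic chi2 at +/-90)."""
    from .library_builder import create_library  # local import: cycle guard

    idx = structure.residue_indices(chain, resnum)
    if not idx:
        raise UnsupportedResidueError(f"no residue {chain}/{resnum}")
    resname = structure.atoms[idx[0]].resname
    if resname not in CHI_DEFS:
        raise UnsupportedResidueError(
            f"residue {resname} {chain}/{resnum} has no rotamer set"
        )
    atoms = [
        Atom(serial=k + 1, name=structure.atoms[i].name,
             element=structure.atoms[i].element, resname=resname,
             resnum=resnum, chain=chain)
        for k, i in enumerate(idx)
    ]
    sub = StructureModel(
        atoms=atoms,
        models=[structure.coords[idx].copy()],
        source_id=f"{resname}{resnum}",
    )
    names = {a.name for a in atoms}
    defs = [q for q in CHI_DEFS[resname] if all(n in names for n in q)]
    base = create_library(
        name=f"{resname}-native", multistate_structure=sub,
        dihedral_defs=defs, spin_atoms=[], spin_weights=[], resname=resname,
    )
    # expand the single observed conformer over the chi grid
    grids = []
    for k, quad in enumerate(defs):
        if k == 1 and resname in _AROMATIC:
            grids.append((-90.0, 90.0))
        else:
            grids.append((-60.0, 60.0, 180.0))
    combos = [[]]
    for g in grids:
        combos = [c + [v] for c in combos for v in g]
    chi = np.asarray(combos, dtype=float).reshape(len(combos), len(defs))
    coords = np.stack([base.coords_for_dihedrals(0, c) for c in chi])
    return RotamerLibrary(
        name=base.name, resname=resname, atom_names=base.atom_names,
        elements=base.elements, coords=coords, dihedral_defs=defs,
        dihedrals=chi, weights=np.full(len(chi), 1.0 / len(chi)),
    )


@dataclass
class _Site:
    site: tuple[str, int]
    ensemble: RotamerEnsemble  # rotamers aligned in the protein frame
    state: int  # current rotamer index
    coords: np.ndarray  # current side-chain atom coords (S, 3)
    dihedrals: np.ndarray  # current mobile dihedrals (K,)

    @property
    def elements(self) -> list[str]:
        return self.ensemble.side_chain_elements


@dataclass
class RepackTrajectory:
    frames: list[dict]  # site -> (rotamer index, coords, dihedrals)
    energies: np.ndarray  # per step, relative to start (kcal/mol)
    accepted: np.ndarray  # per-step accept flag
    region: list[tuple[str, int]]
    rng_seed: object
    protein: StructureModel
    site_libraries: dict
    site_ensembles: dict

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def trajectory_structure(self) -> StructureModel:
        """All frames as one multistate structure (for PDB export)."""
        base = self.frame_structure(0)
        models = [base.models[0]]
        for i in range(1, self.n_frames):
            models.append(self.frame_structure(i).models[0])
        return StructureModel(atoms=base.atoms, models=models,
                              source_id=self.protein.source_id + ":repack")

    def frame_structure(self, i: int) -> StructureModel:
        """Full structure with frame *i*'s side-chain conformations."""
        s = self.protein.copy()
        xyz = s.models[0]
        for site, (_, coords, _) in self.frames[i].items():
            lib = self.site_libraries[site]
            sc_names = [
                n for n, m in zip(lib.atom_names, lib.side_chain_mask) if m
            ]
            for name, c in zip(sc_names, coords):
                try:
                    xyz[s.atom_index(site[0], site[1], name)] = c
                except KeyError:
                    pass  # label atom absent from the native topology
        return s


def _lj_energy(ci, ei, cj, ej, params: energetics.LJParams) -> float:
    """Flat-top repulsive LJ between two raw atom sets (kcal/mol)."""
    if len(ci) == 0 or len(cj) == 0:
        return 0.0
    ri, epi = params.lookup(ei)
    rj, epj = params.lookup(ej)
    d = cdist(ci, cj)
    mask = d <= params.cutoff
    if not mask.any():
        return 0.0
    rmin = ri[:, None] + rj[None, :]
    eps = np.sqrt(epi[:, None] * epj[None, :])
    e = eps[mask] * ((params.forgive * rmin[mask]) / d[mask]) ** 12
    return float(np.minimum(e, params.cap).sum())


def repack(
    structure: StructureModel,
    labels: list[SpinLabel],
    radius: float = DEFAULT_RADIUS,
    n_steps: int = 1000,
    kT: float = energetics.DEFAULT_KT,
    off_rotamer: bool = False,
    rng_seed=None,
    params: energetics.LJParams | None = None,
    energy_func=None,
    include_proposal_ratio: bool = True,
) -> RepackTrajectory:
    """MCMC repack of the label(s) and all side chains within *radius*.

    Acceptance uses the Metropolis-Hastings criterion; because rotamer
    proposals are drawn by prior weight, the proposal ratio q(old)/q(new)
    is included by default (set ``include_proposal_ratio=False`` for plain
    Metropolis). *energy_func* (ensemble, environment, params) -> energies
    overrides the site-vs-static-environment term.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not labels:
        raise ValueError("at least one attached label is required")
    params = params or energetics.LJParams()
    rng = np.random.default_rng(rng_seed)

    label_sites = {l.site for l in labels}
    label_atoms = np.vstack([l.coords.reshape(-1, 3) for l in labels])
    tree = cKDTree(label_atoms)

    # region: residues with any side-chain atom within radius of any label
    # rotamer atom, plus the label sites themselves
    region: list[tuple[str, int]] = []
    for chain, resnum, resname in structure.residues():
        if (chain, resnum) in label_sites:
            continue
        if resname in _FIXED_SIDE_CHAINS or resname in WATER_RESNAMES:
            continue
        if resname not in CHI_DEFS:
            continue  # ligands etc. stay as fixed environment
        sc = [
            i
            for i in structure.residue_indices(chain, resnum)
            if structure.atoms[i].name not in BACKBONE_NAMES
        ]
        if sc and tree.query(structure.coords[sc], k=1)[0].min() <= radius:
            region.append((chain, resnum))
    if not region and not label_sites:
        raise ValueError("empty repack region")

    # per-site rotamer ensembles in the protein frame
    sites: list[_Site] = []
    site_libraries: dict = {}
    for label in labels:
        ens = label
        start = int(np.argmax(ens.weights))
        sites.append(
            _Site(
                site=label.site,
                ensemble=ens,
                state=start,
                coords=ens.side_chain_coords[start].copy(),
                dihedrals=ens.dihedrals[start].copy(),
            )
        )
        site_libraries[label.site] = label.library
    for chain, resnum in region:
        lib = site_rotamer_library(structure, chain, resnum)
        ens = attach(lib, structure, chain, resnum, eval_clash=False)
        start = 0
        sites.append(
            _Site(
                site=(chain, resnum),
                ensemble=ens,
                state=start,
                coords=ens.side_chain_coords[start].copy(),
                dihedrals=ens.dihedrals[start].copy(),
            )
        )
        site_libraries[(chain, resnum)] = lib

    mobile_sites = {s.site for s in sites}
    static_idx = np.array(
        [
            i
            for i, a in enumerate(structure.atoms)
            if a.resname not in WATER_RESNAMES
            and not (
                (a.chain, a.resnum) in mobile_sites
                and a.name not in BACKBONE_NAMES
            )
        ],
        dtype=np.intp,
    )
    static_coords = structure.coords[static_idx]
    static_elems = [structure.atoms[i].element for i in static_idx]
    static_subset = AtomSubset(structure, static_idx)

    def static_energy(site: _Site, coords: np.ndarray,
                      dihedrals: np.ndarray) -> float:
        if energy_func is not None:
            view = RotamerEnsemble(
                library=site.ensemble.library,
                site=site.site,
                coords=_full_coords(site, coords)[None],
                weights=np.ones(1),
                dihedrals=dihedrals[None],
            )
            return float(
                np.asarray(energy_func(view, static_subset, params))[0]
            )
        # restrict to static atoms within cutoff for speed
        return _lj_energy(coords, site.elements, static_coords,
                          static_elems, params)

    def _full_coords(site: _Site, sc_coords: np.ndarray) -> np.ndarray:
        full = site.ensemble.coords[site.state].copy()
        full[site.ensemble.side_chain_mask] = sc_coords
        return full

    def site_energy(k: int, coords: np.ndarray,
                    dihedrals: np.ndarray) -> float:
        e = static_energy(sites[k], coords, dihedrals)
        for j, other in enumerate(sites):
            if j == k:
                continue
            e += _lj_energy(coords, sites[k].elements, other.coords,
                            other.elements, params)
        return e

    def total_energy() -> float:
        e = 0.0
        for k, s in enumerate(sites):
            e += static_energy(s, s.coords, s.dihedrals)
            for j in range(k + 1, len(sites)):
                e += _lj_energy(s.coords, s.elements, sites[j].coords,
                                sites[j].elements, params)
        return e

    def snapshot() -> dict:
        return {
            s.site: (s.state, s.coords.copy(), s.dihedrals.copy())
            for s in sites
        }

    e_start = total_energy()
    e_current = e_start
    frames = [snapshot()]
    energies = np.empty(n_steps)
    accepted = np.zeros(n_steps, dtype=bool)

    for step in range(n_steps):
        k = int(rng.integers(len(sites)))
        s = sites[k]
        prior = s.ensemble.weights
        r_new = int(rng.choice(len(prior), p=prior))
        new_dih = s.ensemble.dihedrals[r_new].copy()
        new_coords = s.ensemble.side_chain_coords[r_new].copy()
        if off_rotamer and s.ensemble.library.n_dihedrals:
            lib = s.ensemble.library
            sig = lib.resolve_sigmas()[min(r_new, lib.n_rotamers - 1)]
            full = s.ensemble.coords[r_new].copy()
            from .rotamer_core import set_dihedral

            for d, (quad, ds) in enumerate(
                zip(lib.dihedral_indices, lib.downstream)
            ):
                if np.isfinite(sig[d]) and sig[d] > 0:
                    new_dih[d] = wrap_angle(new_dih[d] + rng.normal(0, sig[d]))
                    full = set_dihedral(full, quad, ds, new_dih[d])
            new_coords = full[s.ensemble.side_chain_mask]

        e_old = site_energy(k, s.coords, s.dihedrals)
        old_state = s.state
        e_new = site_energy(k, new_coords, new_dih)
        d_e = e_new - e_old
        log_acc = -d_e / kT if np.isfinite(kT) else 0.0
        if include_proposal_ratio:
            log_acc += np.log(prior[old_state]) - np.log(prior[r_new])
        if np.log(rng.uniform()) < min(0.0, log_acc):
            s.state, s.coords, s.dihedrals = r_new, new_coords, new_dih
            e_current += d_e
            accepted[step] = True
            frames.append(snapshot())
        energies[step] = e_current - e_start
        if (step + 1) % 100 == 0:  # bound incremental-energy drift
            e_current = total_energy()

    return RepackTrajectory(
        frames=frames,
        energies=energies,
        accepted=accepted,
        region=[s.site for s in sites],
        rng_seed=rng_seed,
        protein=structure,
        site_libraries=site_libraries,
        site_ensembles={s.site: s.ensemble for s in sites},
    )


def from_trajectory(
    trajectory: RepackTrajectory,
    site: tuple[str, int],
    burn_in: int | None = None,
) -> SpinLabel | RotamerEnsemble:
    """Build a rotamer ensemble for *site* from post-burn-in frames.

    Frames whose mobile dihedrals agree within 1e-6 degrees are merged;
    each unique conformation is weighted by its frame fraction.
    """
    if burn_in is None:
        burn_in = int(DEFAULT_BURN_IN_FRACTION * trajectory.n_frames)
    if not (0 <= burn_in < trajectory.n_frames):
        raise ValueError(
            f"burn_in {burn_in} out of range [0, {trajectory.n_frames})"
        )
    if site not in trajectory.site_libraries:
        raise UnsupportedResidueError(f"site {site} not in repack region")
    lib = trajectory.site_libraries[site]

    ens = trajectory.site_ensembles[site]
    ens_mask = ens.side_chain_mask
    confs: list[tuple[np.ndarray, np.ndarray]] = []  # (dihedrals, full coords)
    counts: list[int] = []
    for frame in trajectory.frames[burn_in:]:
        state, sc_coords, dih = frame[site]
        for i, (d0, c0) in enumerate(confs):
            if len(dih):
                same = np.all(np.abs(wrap_angle(dih - d0)) <= 1e-6)
            else:
                same = np.allclose(sc_coords, c0[ens_mask], atol=1e-9)
            if same:
                counts[i] += 1
                break
        else:
            full = ens.coords[min(state, ens.n_rotamers - 1)].copy()
            full[ens_mask] = sc_coords
            confs.append((dih.copy(), full))
            counts.append(1)

    weights = np.asarray(counts, dtype=float)
    weights /= weights.sum()
    coords = np.stack([c for _, c in confs])
    dihedrals = np.stack([d for d, _ in confs]) if confs[0][0].size else (
        np.zeros((len(confs), 0))
    )
    common = dict(
        library=lib,
        site=site,
        coords=coords,
        weights=weights,
        dihedrals=dihedrals,
        provenance={"method": "trajectory", "burn_in": burn_in,
                    "n_frames": trajectory.n_frames},
    )
    if lib.spin_atoms:
        return SpinLabel(
            spin_atoms=list(lib.spin_atoms),
            spin_weights=np.asarray(lib.spin_weights, dtype=float),
            **common,
        )
    return RotamerEnsemble(**common)


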