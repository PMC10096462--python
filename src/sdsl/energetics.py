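"""Clash scoring, Boltzmann reweighting, trimming and solvent accessibility.

The default rotamer score is a flat-top purely repulsive Lennard-Jones
12-power: per atom pair within the cutoff,

    E_pair = min(E_cap, eps_ij * ((f * rmin_ij) / r_ij)**12)

with rmin_ij = rmin_i/2 + rmin_j/2, eps_ij = sqrt(eps_i * eps_j) and f the
forgive factor. An optional full 12-6 variant and a SASA-augmented score
are provided for comparison; any callable with the signature
``(ensemble, environment, params) -> per-rotamer energies (kcal/mol)``
can be plugged into attachment and repacking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateWeightsError, UnknownElementError

DEFAULT_KT = 0.593  # kcal/mol at 298 K
DEFAULT_TRIM_TOL = 0.005
DEFAULT_FORGIVE = 0.9
DEFAULT_CAP = 10.0  # kcal/mol
DEFAULT_CUTOFF = 10.0  # Å
DEFAULT_PROBE = 1.4  # Å
DEFAULT_SASA_POINTS = 256

__all__ = [
    "LJParams",
    "flat_top_repulsive_lj",
    "lennard_jones_12_6",
    "sasa_augmented_energy",
    "reweight",
    "trim_indices",
    "trim",
    "shrake_rupley_sasa",
]


CONFIG_KEYS = {
    "forgive": float,
    "cap": float,
    "cutoff": float,
    "kT": float,
    "trim_tol": float,
    "lj_table_path": str,
    "sasa.probe": float,
    "sasa.n_points": int,
}


def load_config(path: str | Path) -> dict:
    """Parse a key-value config file (``key = value`` or ``key: value``,
    '#' comments). Unknown keys raise; values are coerced per key."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, value = (s.strip() for s in line.split(sep, 1))
                break
        else:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        if key not in CONFIG_KEYS:
            raise ValueError(
                f"config line {lineno}: unknown key {key!r} "
                f"(known: {sorted(CONFIG_KEYS)})"
            )
        out[key] = CONFIG_KEYS[key](value)
    return out


def _load_table(path: str | Path | None) -> dict[str, tuple[float, float]]:
    if path is None:
        text = (
            resources.files("sdsl.data").joinpath("lj_params.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)["elements"]
    return {
        el.capitalize(): (float(v["rmin_half"]), float(v["epsilon"]))
        for el, v in raw.items()
    }


@dataclass
class LJParams:
    """Lennard-Jones clash-scoring parameters."""

    forgive: float = DEFAULT_FORGIVE
    cap: float = DEFAULT_CAP
    cutoff: float = DEFAULT_CUTOFF
    table_path: str | Path | None = None
    table: dict = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.forgive <= 1.2):
            raise ValueError(f"forgive must be in (0, 1.2], got {self.forgive}")
        if self.cap <= 0 or self.cutoff <= 0:
            raise ValueError("cap and cutoff must be positive")
        if self.table is None:
            self.table = _load_table(self.table_path)

    def lookup(self, elements) -> tuple[np.ndarray, np.ndarray]:
        """Per-atom (rmin/2, epsilon) arrays; unknown element raises."""
        rmin, eps = [], []
        for el in elements:
            key = el.capitalize()
            if key not in self.table:
                raise UnknownElementError(
                    f"element {el!r} missing from the Lennard-Jones table"
                )
            r, e = self.table[key]
            rmin.append(r)
            eps.append(e)
        return np.asarray(rmin), np.asarray(eps)


def _pairwise_terms(ensemble, environment, params: LJParams):
    """Shared pair bookkeeping for the LJ variants.

    Yields, per rotamer, (r, rmin_ij, eps_ij) over environment atoms within
    the cutoff of any of that rotamer's side-chain atoms.
    """
    env_coords = environment.coords
    env_elems = [a.element for a in environment.atoms]
    rmin_env, eps_env = params.lookup(env_elems)
    rmin_lab, eps_lab = params.lookup(ensemble.clash_elements)
    tree = cKDTree(env_coords) if len(env_coords) else None
    for r in range(ensemble.n_rotamers):
        sc = ensemble.clash_coords[r]
        if tree is None or len(sc) == 0:
            yield (np.zeros(0), np.zeros(0), np.zeros(0))
            continue
        pairs = tree.query_ball_point(sc, params.cutoff)
        ai, ej = [], []
        for i, js in enumerate(pairs):
            ai.extend([i] * len(js))
            ej.extend(js)
        ai = np.asarray(ai, dtype=np.intp)
        ej = np.asarray(ej, dtype=np.intp)
        if ai.size == 0:
            yield (np.zeros(0), np.zeros(0), np.zeros(0))
            continue
        d = np.linalg.norm(sc[ai] - env_coords[ej], axis=1)
        d = np.maximum(d, 1e-12)  # coincident atoms hit the cap anyway
        yield (
            d,
            rmin_lab[ai] + rmin_env[ej],
            np.sqrt(eps_lab[ai] * eps_env[ej]),
        )


def flat_top_repulsive_lj(ensemble, environment, params: LJParams | None = None):
    """Per-rotamer flat-top repulsive Lennard-Jones energies (kcal/mol)."""
    params = params or LJParams()
    out = np.zeros(ensemble.n_rotamers)
    for r, (d, rmin, eps) in enumerate(
        _pairwise_terms(ensemble, environment, params)
    ):
        if d.size == 0:
            continue
        e = eps * ((params.forgive * rmin) / d) ** 12
        out[r] = np.minimum(e, params.cap).sum()
    return out


def lennard_jones_12_6(ensemble, environment, params: LJParams | None = None):
    """Full 12-6 Lennard-Jones variant (attractive term included); each pair
    energy capped above at E_cap."""
    params = params or LJParams()
    out = np.zeros(ensemble.n_rotamers)
    for r, (d, rmin, eps) in enumerate(
        _pairwise_terms(ensemble, environment, params)
    ):
        if d.size == 0:
            continue
        ratio = (params.forgive * rmin) / d
        e = eps * (ratio**12 - 2.0 * ratio**6)
        out[r] = np.minimum(e, params.cap).sum()
    return out


def reweight(prior_weights, energies, kT: float = DEFAULT_KT) -> np.ndarray:
    """Boltzmann-reweight prior weights by per-rotamer energies.

    w_i ∝ prior_i * exp(-E_i / kT); invariant under a constant energy shift.
    """
    prior = np.asarray(prior_weights, dtype=float)
    e = np.asarray(energies, dtype=float)
    if prior.shape != e.shape:
        raise ValueError("prior_weights and energies must have equal length")
    if kT <= 0:
        raise ValueError(f"kT must be positive, got {kT}")
    logw = np.where(prior > 0, np.log(np.where(prior > 0, prior, 1.0)), -np.inf)
    logw = logw - e / kT
    m = logw.max()
    if not np.isfinite(m):
        raise DegenerateWeightsError("all posterior weight mass vanished")
    w = np.exp(logw - m)
    total = w.sum()
    if total == 0 or not np.isfinite(total):
        raise DegenerateWeightsError("posterior weights underflowed")
    return w / total


def trim_indices(weights, trim_tol: float = DEFAULT_TRIM_TOL) -> np.ndarray:
    """Indices (sorted ascending) of the smallest weight-sorted prefix whose
    cumulative weight reaches 1 - trim_tol; at least one rotamer survives."""
    if not (0.0 <= trim_tol < 1.0):
        raise ValueError(f"trim_tol must be in [0, 1), got {trim_tol}")
    w = np.asarray(weights, dtype=float)
    order = np.argsort(w)[::-1]
    cum = np.cumsum(w[order])
    # number kept: first k with cum_k >= 1 - trim_tol
    k = int(np.searchsorted(cum, 1.0 - trim_tol) + 1)
    k = min(max(k, 1), len(w))
    if trim_tol == 0.0:
        keep = order[w[order] > 0]
        if keep.size == 0:
            keep = order[:1]
        return np.sort(keep)
    return np.sort(order[:k])


def trim(ensemble, trim_tol: float = DEFAULT_TRIM_TOL):
    """Return the ensemble with low-weight rotamers removed and weights
    renormalized (relative weights among survivors preserved)."""
    keep = trim_indices(ensemble.weights, trim_tol)
    ensemble.coords = ensemble.coords[keep]
    ensemble.dihedrals = ensemble.dihedrals[keep]
    w = ensemble.weights[keep]
    ensemble.weights = w / w.sum()
    return ensemble


# ---------------------------------------------------------------------------
# Solvent-accessible surface area

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [
            np.sin(phi) * np.cos(theta),
            np.sin(phi) * np.sin(theta),
            np.cos(phi),
        ]
    )


def shrake_rupley_sasa(
    coords,
    radii,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Ų), Shrake-Rupley method.

    Each atom's sphere of radius r_i + probe is sampled with *n_points*
    quasi-uniform points; the accessible fraction (points outside every
    neighbor's expanded sphere) times the sphere area gives the atom's SASA.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    expanded = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(n)
    rmax = expanded.max() if n else 0.0
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        free = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], expanded[i] + rmax):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            free &= d2 > expanded[j] ** 2
        out[i] = free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out


def sasa_radii(params: LJParams, elements) -> np.ndarray:
    """Atomic radii for SASA: the LJ table's rmin/2 values."""
    rmin, _ = params.lookup(elements)
    return rmin


def sasa_augmented_energy(
    ensemble,
    environment,
    params: LJParams | None = None,
    w_sasa: float = 0.1,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
):
    """Flat-top repulsive LJ minus an attractive term proportional to each
    rotamer's side-chain SASA computed in the environment context.

    Rewards solvent-exposed rotamers to compensate for neglected
    label-solvent dispersion; conforms to the energy-function contract.
    """
    params = params or LJParams()
    if w_sasa < 0:
        raise ValueError("w_sasa must be >= 0")
    e_lj = flat_top_repulsive_lj(ensemble, environment, params)
    if w_sasa == 0.0:
        return e_lj
    env_coords = environment.coords
    env_radii = sasa_radii(params, [a.element for a in environment.atoms])
    lab_radii = sasa_radii(params, ensemble.clash_elements)
    # only environment atoms this close can occlude a label atom
    reach = 2.0 * (max(env_radii.max(initial=0.0), lab_radii.max()) + probe)
    env_tree = cKDTree(env_coords) if len(env_coords) else None
    out = np.empty(ensemble.n_rotamers)
    for r in range(ensemble.n_rotamers):
        sc = ensemble.clash_coords[r]
        if env_tree is not None:
            near = sorted(
                {j for js in env_tree.query_ball_point(sc, reach) for j in js}
            )
        else:
            near = []
        coords = np.vstack([sc, env_coords[near]]) if near else sc
        radii = np.concatenate([lab_radii, env_radii[near]])
        areas = shrake_rupley_sasa(coords, radii, probe=probe, n_points=n_points)
        out[r] = e_lj[r] - w_sasa * areas[: len(sc)].sum()
    return out
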