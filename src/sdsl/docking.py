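"""Rigid-body membrane docking from per-site spin-label depth restraints.

The membrane frame puts the phosphate plane at z = 0 with positive z into
the hydrocarbon core. A pose is (z_offset, alpha, beta, gamma): rotation of
the protein about its reference center by Z-Y-Z Euler angles — applied as
Rz(alpha), then Ry(beta), then Rz(gamma) about the fixed axes — followed by
a translation along z. gamma rotates about the membrane normal and is
therefore unconstrained by planar depth data; it is reported but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .errors import MissingSiteError, UnderDeterminedError
from .rotamer_core import RigidTransform

__all__ = [
    "DepthRecord",
    "DepthDataset",
    "DockingPose",
    "pose_transform",
    "depth_residuals",
    "fit_membrane_pose",
]


@dataclass(frozen=True)
class DepthRecord:
    chain: str
    resnum: int
    depth: float  # Å relative to the phosphate plane
    sigma: float | None = None  # optional uncertainty, Å


@dataclass
class DepthDataset:
    records: list[DepthRecord]

    def __post_init__(self) -> None:
        sites = [(r.chain, r.resnum) for r in self.records]
        if len(set(sites)) != len(sites):
            raise ValueError("duplicate sites in depth dataset")
        for r in self.records:
            if not np.isfinite(r.depth):
                raise ValueError(f"non-finite depth at {r.chain}/{r.resnum}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sites(self) -> list[tuple[str, int]]:
        return [(r.chain, r.resnum) for r in self.records]

    @property
    def depths(self) -> np.ndarray:
        return np.array([r.depth for r in self.records])

    @classmethod
    def from_text(cls, text: str) -> "DepthDataset":
        """Parse a whitespace-delimited ``chain resnum depth [sigma]`` table;
        '#' starts a comment."""
        records = []
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"bad depth-table line: {line!r}")
            records.append(
                DepthRecord(
                    chain=parts[0],
                    resnum=int(parts[1]),
                    depth=float(parts[2]),
                    sigma=float(parts[3]) if len(parts) == 4 else None,
                )
            )
        return cls(records)

    def to_text(self) -> str:
        lines = ["# chain resnum depth [sigma]"]
        for r in self.records:
            line = f"{r.chain} {r.resnum} {r.depth:.3f}"
            if r.sigma is not None:
                line += f" {r.sigma:.3f}"
            lines.append(line)
        return "\n".join(lines) + "\n"


@dataclass
class DockingPose:
    z_offset: float = 0.0
    alpha: float = 0.0  # deg
    beta: float = 0.0  # deg
    gamma: float = 0.0  # deg, unconstrained by planar depth data
    center: np.ndarray | None = None  # rotation center (protein centroid)
    residuals: np.ndarray | None = None  # Å, per dataset site
    ssr: float | None = None
    gamma_constrained: bool = False

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_euler(
            "zyz", [self.alpha, self.beta, self.gamma], degrees=True
        ).as_matrix()

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


def euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of DockingPose.rotation (degenerate at beta in {0, 180})."""
    a, b, g = Rotation.from_matrix(R).as_euler("zyz", degrees=True)
    return float(a), float(b), float(g)


def pose_transform(pose: DockingPose) -> RigidTransform:
    """Rigid transform of a pose: rotate about the pose center, then
    translate by (0, 0, z_offset)."""
    center = np.zeros(3) if pose.center is None else np.asarray(pose.center)
    R = pose.rotation
    t = center - R @ center + np.array([0.0, 0.0, pose.z_offset])
    return RigidTransform(R, t)


def depth_residuals(
    pose: DockingPose,
    spin_centroids: dict[tuple[str, int], np.ndarray],
    dataset: DepthDataset,
    weighted: bool = False,
) -> np.ndarray:
    """Per-site residuals z(transformed centroid) - measured depth (Å);
    with *weighted*, each residual is divided by the site's uncertainty."""
    tf = pose_transform(pose)
    out = np.empty(len(dataset))
    for i, rec in enumerate(dataset.records):
        site = (rec.chain, rec.resnum)
        if site not in spin_centroids:
            raise MissingSiteError(f"no spin centroid for site {site}")
        z = tf.apply(np.asarray(spin_centroids[site], dtype=float))[2]
        r = z - rec.depth
        if weighted and rec.sigma is not None:
            r /= rec.sigma
        out[i] = r
    return out


def fit_membrane_pose(
    spin_centroids: dict[tuple[str, int], np.ndarray],
    dataset: DepthDataset,
    init_pose: DockingPose | None = None,
    n_restarts: int = 8,
    rng_seed=None,
    weighted: bool = False,
) -> DockingPose:
    """Least-squares membrane pose from depth restraints.

    Minimizes the sum of squared depth residuals over (z_offset, alpha,
    beta) — gamma is fixed at 0, being a rotation about the membrane normal
    that the data cannot constrain — using Nelder-Mead simplex from
    *n_restarts* dispersed orientations (plus *init_pose* if given). The
    rotation center is the centroid of the fitted sites' spin centroids.
    Deterministic: restarts are a fixed grid; *rng_seed* is accepted for
    interface symmetry but unused.
    """
    if len(dataset) < 2:
        raise UnderDeterminedError(
            f"{len(dataset)} depth restraint(s); at least 2 required "
            "(>= 4 recommended)"
        )
    pts = np.array(
        [
            spin_centroids[site]
            if site in spin_centroids
            else _missing(site)
            for site in dataset.sites
        ]
    )
    center = pts.mean(axis=0)

    def ssr(x) -> float:
        pose = DockingPose(
            z_offset=x[0], alpha=x[1], beta=x[2], gamma=0.0, center=center
        )
        r = depth_residuals(pose, spin_centroids, dataset, weighted=weighted)
        return float(r @ r)

    starts = []
    if init_pose is not None:
        starts.append([init_pose.z_offset, init_pose.alpha, init_pose.beta])
    mean_depth = float(dataset.depths.mean())
    k = 0
    while len(starts) < n_restarts + (init_pose is not None):
        beta0 = (k % 4) * 60.0
        alpha0 = 0.0 if k < 4 else 180.0
        starts.append([mean_depth - center[2], alpha0, beta0])
        k += 1

    best = None
    for x0 in starts:
        res = minimize(
            ssr,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-8,
                "fatol": 1e-12,
                "maxiter": 2000,
                "maxfev": 4000,
            },
        )
        if best is None or res.fun < best.fun:
            best = res

    x = best.x
    alpha, beta = x[1], x[2] % 360.0
    if beta > 180.0:  # canonicalize: beta in [0, 180], flip absorbed by alpha
        beta = 360.0 - beta
        alpha += 180.0
    alpha = (alpha + 180.0) % 360.0 - 180.0
    pose = DockingPose(
        z_offset=float(x[0]),
        alpha=float(alpha),
        beta=float(beta),
        gamma=0.0,
        center=center,
        gamma_constrained=False,
    )
    pose.residuals = depth_residuals(pose, spin_centroids, dataset,
                                     weighted=weighted)
    pose.ssr = float(pose.residuals @ pose.residuals)
    return pose


def _missing(site):
    raise MissingSiteError(f"no spin centroid for site {site}")
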