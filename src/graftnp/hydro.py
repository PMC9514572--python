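"""Path-integration (electrostatic analogy) solution-property estimators.

The hydrodynamic radius of a rigid body is approximated by the electrostatic
capacity C of a conductor of the same shape (R_h ~ C, accurate to about 1%),
in units where the capacity of a sphere equals its radius.  C is computed by
walk-on-spheres Monte Carlo: walkers launched from an enclosing sphere step
by the distance to the body surface and are absorbed within a thin skin;
walkers that wander outside the launch sphere are returned through the exact
first-passage re-entry distribution or counted as escaped, and
C = b * (absorbed fraction) for launch radius b.

The same walker machinery yields the orientation-averaged electric
polarizability <alpha> of the conductor (normalized so a sphere has
alpha = 3V), from which the intrinsic viscosity follows as
[eta] = (5/6) <alpha> / V with V the body volume; the prefactor is fixed by
the sphere calibration [eta] = 5/2.

Bodies are unions of spheres (the natural carrier for bead-spring
configurations); distances to the union are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .engine import GraftedNPConfig

__all__ = [
    "SphereUnionBody",
    "HydroEstimate",
    "GyrationResult",
    "distance_to_body",
    "capacity",
    "hydrodynamic_radius",
    "gyration",
    "rh_rg_ratio",
    "intrinsic_viscosity",
    "body_from_config",
]


@dataclass
class SphereUnionBody:
    """Geometric union of spheres: centers (M, 3) and positive radii (M,)."""

    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.centers) != len(self.radii) or len(self.radii) == 0:
            raise ValueError("need one positive radius per center")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    def __len__(self) -> int:
        return len(self.radii)

    def centroid(self) -> np.ndarray:
        return self.centers.mean(axis=0)

    def launch_sphere(self) -> Tuple[np.ndarray, float]:
        """Enclosing sphere: centered on the centroid, 1% inflated."""
        c = self.centroid()
        b = float(np.max(np.linalg.norm(self.centers - c, axis=1)
                         + self.radii)) * 1.01
        return c, b

    def scaled(self, lam: float) -> "SphereUnionBody":
        return SphereUnionBody(self.centers * lam, self.radii * lam)

    def add_sphere(self, center, radius: float) -> "SphereUnionBody":
        return SphereUnionBody(np.vstack([self.centers, center]),
                               np.append(self.radii, radius))

    def _groups(self):
        """Spheres sorted into equal-radius groups for the fast kernel."""
        order = np.argsort(self.radii, kind="stable")
        radii = self.radii[order]
        centers = np.ascontiguousarray(self.centers[order])
        boundaries = np.flatnonzero(np.diff(radii)) + 1
        group_start = np.concatenate(
            ([0], boundaries, [len(radii)])).astype(np.int64)
        group_radius = radii[group_start[:-1]]
        return centers, group_start, np.ascontiguousarray(group_radius)


@dataclass
class HydroEstimate:
    """A Monte Carlo property estimate with its sampling metadata."""

    value: float
    std_error: float
    n_walks: int
    skin: float
    launch_radius: float
    seed: int
    extra: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


@dataclass
class GyrationResult:
    tensor: np.ndarray
    eigenvalues: np.ndarray  # Lambda1 <= Lambda2 <= Lambda3 (nm^2)
    R_g: float
    contrast_mode: str


def body_from_config(config: GraftedNPConfig, include_core: bool = True,
                     bead_radius: float = 0.325) -> SphereUnionBody:
    """Sphere union of one snapshot: core sphere plus sigma/2 beads
    (default bead radius 0.325 nm for sigma = 0.65 nm)."""
    centers = [np.asarray(config.bead_positions, dtype=float)]
    radii = [np.full(len(config.bead_positions), bead_radius)]
    if config.core is not None and include_core:
        centers.append(config.core.center[None, :])
        radii.append(np.array([config.core.radius]))
    return SphereUnionBody(np.vstack(centers), np.concatenate(radii))


def distance_to_body(point, body: SphereUnionBody):
    """Signed distance from point(s) to the union surface (negative inside).

    Exact for sphere unions: min over spheres of |p - c_i| - r_i.
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    d = (np.linalg.norm(p[:, None, :] - body.centers[None, :, :], axis=-1)
         - body.radii[None, :]).min(axis=1)
    return d[0] if np.ndim(point) == 1 else d


def _seed32(seed: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence((seed, salt)).generate_state(1)[0]
               % 2**31)


def _run_walker(body: SphereUnionBody, n_walks: int, skin: float,
                seed: int, n_batches: int, max_steps: int):
    centers, group_start, group_radius = body._groups()
    c, b = body.launch_sphere()
    hits = np.zeros(n_batches, dtype=np.int64)
    sum_y = np.zeros((n_batches, 3))
    sum_ny = np.zeros((n_batches, 3, 3))
    capped = _kernels.wos_walk(
        centers, group_start, group_radius, c[0], c[1], c[2], b,
        int(n_walks), skin, _seed32(seed), max_steps, n_batches,
        hits, sum_y, sum_ny)
    per_batch = int(n_walks) // n_batches
    return c, b, hits, sum_y, sum_ny, capped, per_batch


def capacity(body: SphereUnionBody, n_walks: int = 100_000,
             skin: Optional[float] = None, seed: int = 0,
             n_batches: int = 20, max_steps: int = 100_000) -> HydroEstimate:
    """Electrostatic capacity of the body by walk-on-spheres.

    The default skin is 1e-4 of the launch radius; the finite-skin bias is
    first order in the skin and below the Monte Carlo error at defaults.
    """
    if n_walks < 1_000:
        raise ValueError("need at least 1e3 walks")
    _, b0 = body.launch_sphere()
    if skin is None:
        skin = 1e-4 * b0
    if skin >= body.radii.min():
        raise ValueError("skin must be far below the smallest sphere radius")
    c, b, hits, _, _, capped, per_batch = _run_walker(
        body, n_walks, skin, seed, n_batches, max_steps)
    n = per_batch * len(hits)
    p = hits.sum() / n
    se = b * np.sqrt(max(p * (1.0 - p), 1e-300) / n)
    extra = {"n_hits": int(hits.sum()), "capped_walks": int(capped)}
    if capped:
        extra["bias_warning"] = "walker step cap exceeded; estimate biased low"
    return HydroEstimate(value=b * p, std_error=float(se), n_walks=n,
                         skin=skin, launch_radius=b, seed=seed, extra=extra)


def hydrodynamic_radius(body: SphereUnionBody, **kwargs) -> HydroEstimate:
    """R_h of the body through the capacity analogy (accuracy about 1%)."""
    est = capacity(body, **kwargs)
    est.extra["interpretation"] = "R_h ~ C (capacity analogy, ~1%)"
    return est


def _weights(body: SphereUnionBody, contrast_mode: str,
             core_index: Optional[int]) -> np.ndarray:
    if contrast_mode == "uniform":
        return body.radii**3
    if contrast_mode == "core_only":
        if core_index is None:
            raise ValueError("core_only contrast needs a core sphere")
        w = np.zeros(len(body))
        w[core_index] = 1.0
        return w
    if contrast_mode == "chains_only":
        if core_index is None:
            raise ValueError("chains_only contrast on a body with no core")
        w = body.radii**3
        w[core_index] = 0.0
        if not w.any():
            raise ValueError("chains_only contrast on a bare core: undefined")
        return w
    raise ValueError(f"unknown contrast mode {contrast_mode!r}")


def gyration(obj, contrast_mode: str = "uniform") -> GyrationResult:
    """Contrast-weighted gyration tensor of a body or configuration.

    Spheres carry mass proportional to radius^3 ("uniform" contrast, i.e.
    equal mass density) and contribute their solid-sphere self term
    (1/5) r^2 I about their own center; "core_only"/"chains_only" restrict
    the weight to the core sphere or to the beads (X-ray- and neutron-like
    contrast).
    """
    core_index = None
    if isinstance(obj, GraftedNPConfig):
        body = body_from_config(obj)
        if obj.core is not None:
            core_index = len(body) - 1
    else:
        body = obj
        if contrast_mode in ("core_only", "chains_only") and len(body) > 1:
            # for a plain body the largest sphere plays the core
            core_index = int(np.argmax(body.radii))
    w = _weights(body, contrast_mode, core_index)
    w = w / w.sum()
    com = w @ body.centers
    d = body.centers - com
    tensor = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    tensor += np.eye(3) * float(w @ (body.radii**2 / 5.0))
    lam = np.sort(np.linalg.eigvalsh(tensor))
    return GyrationResult(tensor=tensor, eigenvalues=lam,
                          R_g=float(np.sqrt(lam.sum())),
                          contrast_mode=contrast_mode)


def rh_rg_ratio(obj, contrast_mode: str = "uniform",
                **capacity_kwargs) -> HydroEstimate:
    """R_h / R_g with the capacity standard error propagated."""
    body = body_from_config(obj) if isinstance(obj, GraftedNPConfig) else obj
    rh = hydrodynamic_radius(body, **capacity_kwargs)
    rg = gyration(obj, contrast_mode).R_g
    return HydroEstimate(value=rh.value / rg, std_error=rh.std_error / rg,
                         n_walks=rh.n_walks, skin=rh.skin,
                         launch_radius=rh.launch_radius, seed=rh.seed,
                         extra={"R_g": rg, "contrast_mode": contrast_mode})


def union_volume(body: SphereUnionBody, n_samples: int = 1_000_000,
                 seed: int = 0, n_batches: int = 20):
    """Monte Carlo volume of the union (uniform sampling in the launch
    ball).  Returns (volume, std_error)."""
    centers, group_start, group_radius = body._groups()
    c, b = body.launch_sphere()
    hits = np.zeros(n_batches, dtype=np.int64)
    _kernels.union_volume_hits(centers, group_start, group_radius,
                               c[0], c[1], c[2], b, int(n_samples),
                               _seed32(seed, 1), n_batches, hits)
    n = (int(n_samples) // n_batches) * n_batches
    vb = 4.0 / 3.0 * np.pi * b**3
    p = hits.sum() / n
    return vb * p, vb * np.sqrt(p * (1.0 - p) / n)


def intrinsic_viscosity(body: SphereUnionBody, n_walks: int = 100_000,
                        n_volume: int = 1_000_000, seed: int = 0,
                        skin: Optional[float] = None, n_batches: int = 20,
                        max_steps: int = 100_000) -> HydroEstimate:
    """Intrinsic viscosity [eta] = lim (eta - eta_s)/(eta_s phi) of the body.

    Computed through the polarizability route: the orientation-averaged
    conductor polarizability <alpha> is estimated from the launch-direction
    x hit-position second moment of the capacity walkers (with the
    neutralizing monopole term subtracted), and [eta] = (5/6) <alpha> / V.
    Dimensionless and scale invariant; exact in expectation for a sphere.
    """
    _, b0 = body.launch_sphere()
    if skin is None:
        skin = 1e-4 * b0
    c, b, hits, sum_y, sum_ny, capped, per_batch = _run_walker(
        body, n_walks, skin, seed, n_batches, max_steps)
    # per-batch orientation-averaged polarizability (4*pi convention:
    # alpha_sphere = 3 V): tr(alpha)/3 = (4pi/3) [tr(m) - sum_j Q_j <y_j>]
    alphas = np.empty(n_batches)
    for k in range(n_batches):
        nb = per_batch
        h = hits[k]
        if h == 0:
            raise RuntimeError("no walker absorbed in a batch; body too small"
                               " relative to the launch sphere?")
        m_tr = 3.0 * b * b * np.trace(sum_ny[k]) / nb
        q = b * sum_y[k] / nb          # Q_j
        ymean = sum_y[k] / h           # <y_j> over hits
        alphas[k] = (4.0 * np.pi / 3.0) * (m_tr - q @ ymean)
    alpha = alphas.mean()
    alpha_se = alphas.std(ddof=1) / np.sqrt(n_batches)
    vol, vol_se = union_volume(body, n_volume, seed=seed,
                               n_batches=n_batches)
    if vol_se / vol > 0.01:
        raise ValueError(
            f"volume estimate relative error {vol_se / vol:.3%} > 1%: "
            "increase n_volume")
    eta = (5.0 / 6.0) * alpha / vol
    se = abs(eta) * np.sqrt((alpha_se / alpha) ** 2 + (vol_se / vol) ** 2)
    extra = {"alpha": alpha, "alpha_se": alpha_se, "volume": vol,
             "volume_se": vol_se, "capped_walks": int(capped)}
    return HydroEstimate(value=float(eta), std_error=float(se),
                         n_walks=per_batch * n_batches, skin=skin,
                         launch_radius=b, seed=seed, extra=extra)
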