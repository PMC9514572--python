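"""Fixtures, file I/O and run manifests.

Canonical test bodies (sphere, tangent dumbbell, medial-axis ellipsoid
tessellation, sphere with N tangent satellites, dandelion of radial bead
rods, grafted NP) are generated deterministically from (name, params, seed);
configurations round-trip through extended-XYZ (plain text, 9 significant
digits) or HDF5 (full precision).  Coordinates are Cartesian nm with the
core at the origin; there is no periodic boundary (isolated particle in
unbounded solvent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from . import __version__
from .engine import GraftedNPConfig, build_grafted_np, _chain_seed
from .forcefield import CoreSpec, ForceField
from .hydro import SphereUnionBody

__all__ = [
    "Fixture",
    "make_fixture",
    "ellipsoid_tessellation",
    "write_configuration",
    "read_configuration",
    "write_manifest",
]

FIXTURE_NAMES = ("sphere", "tangent_dumbbell", "ellipsoid_tessellation",
                 "sphere_with_N_tangent_spheres", "dandelion_rods",
                 "grafted_np")


@dataclass
class Fixture:
    name: str
    obj: Union[SphereUnionBody, GraftedNPConfig]
    params: dict
    seed: int
    provenance: dict = field(default_factory=dict)


def ellipsoid_tessellation(a: float, b: float,
                           n_spheres: int = 600) -> SphereUnionBody:
    """Prolate spheroid (semi-axes a >= b) as a union of spheres.

    Uses the medial-axis transform: the spheroid is exactly the union of its
    maximal inscribed spheres, centered on the major axis at |x| <= c^2/a
    (c^2 = a^2 - b^2) with radius b sqrt(1 - x^2/c^2).  A finite set of
    n_spheres centers leaves only a scalloping error O((dx)^2) on the
    surface; convergence is checked by doubling the resolution.
    """
    if not a >= b > 0:
        raise ValueError("need a >= b > 0")
    if a == b:
        return SphereUnionBody(np.zeros((1, 3)), np.array([b]))
    c2 = a * a - b * b
    xm = c2 / a
    x = np.linspace(-xm, xm, int(n_spheres))
    r = b * np.sqrt(np.maximum(1.0 - x**2 / c2, 0.0))
    keep = r > 0
    centers = np.zeros((keep.sum(), 3))
    centers[:, 2] = x[keep]
    return SphereUnionBody(centers, r[keep])


def _unit_sphere_points(n: int, seed: int) -> np.ndarray:
    pts = np.empty((n, 3))
    for i in range(n):
        rng = _chain_seed(seed, i)
        v = rng.normal(size=3)
        pts[i] = v / np.linalg.norm(v)
    return pts


def make_fixture(name: str, params: dict, seed: int = 0) -> Fixture:
    """Deterministic canonical geometry; regeneration from (name, params,
    seed) is bit-identical."""
    p = dict(params)
    if name == "sphere":
        obj = SphereUnionBody(np.zeros((1, 3)), np.array([p["R"]]))
    elif name == "tangent_dumbbell":
        R, r = p["R"], p["r"]
        obj = SphereUnionBody(np.array([[0.0, 0.0, 0.0],
                                        [0.0, 0.0, R + r]]),
                              np.array([R, r]))
    elif name == "ellipsoid_tessellation":
        obj = ellipsoid_tessellation(p["a"], p["b"],
                                     p.get("n_spheres", 600))
    elif name == "sphere_with_N_tangent_spheres":
        R, r, N = p["R"], p["r"], p["N"]
        centers = [np.zeros(3)]
        radii = [R]
        placed = 0
        i = 0
        while placed < N:
            if i >= 200 * max(N, 1):
                raise ValueError(
                    f"cannot place {N} non-overlapping tangent spheres "
                    f"(max feasible about {placed})")
            rng = _chain_seed(seed, i)
            i += 1
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * (R + r)
            if placed and np.min(np.linalg.norm(
                    np.array(centers[1:]) - v, axis=1)) < 2 * r:
                continue
            centers.append(v)
            radii.append(r)
            placed += 1
        obj = SphereUnionBody(np.array(centers), np.array(radii))
    elif name == "dandelion_rods":
        R = p["R"]
        n_rods = p["n_rods"]
        n_beads = p["n_beads"]
        rb = p.get("bead_radius", 0.325)
        dirs = _unit_sphere_points(n_rods, seed)
        centers = [np.zeros(3)]
        radii = [R]
        for d in dirs:
            for k in range(n_beads):
                centers.append(d * (R + (2 * k + 1) * rb))
                radii.append(rb)
        obj = SphereUnionBody(np.array(centers), np.array(radii))
    elif name == "grafted_np":
        ff = ForceField(**p.get("forcefield", {}))
        obj = build_grafted_np(p["R"], p["N_c"], p["L"], ff, seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"known: {FIXTURE_NAMES}")
    return Fixture(name=name, obj=obj, params=p, seed=seed,
                   provenance={"generator": f"graftnp {__version__}",
                               "name": name, "params": p, "seed": seed})


# ---------------------------------------------------------------------------
# extended XYZ / HDF5 I/O
# ---------------------------------------------------------------------------
def _config_meta(cfg: GraftedNPConfig) -> dict:
    meta = {"kind": "config", "L": cfg.L, "N_c": cfg.N_c}
    if cfg.core is not None:
        meta["core_radius"] = cfg.core.radius
        meta["core_center"] = list(cfg.core.center)
    if cfg.anchor_points is not None:
        meta["anchors"] = np.asarray(cfg.anchor_points).tolist()
    return meta


def write_configuration(path, obj, bead_radius: float = 0.325) -> None:
    """Write a SphereUnionBody or GraftedNPConfig to .xyz (extended) or
    .h5/.hdf5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(path, obj, bead_radius)
        return
    lines = []
    if isinstance(obj, GraftedNPConfig):
        meta = _config_meta(obj)
        n = obj.n_beads() + (1 if obj.core is not None else 0)
        lines.append(str(n))
        lines.append(json.dumps(meta))
        if obj.core is not None:
            cx, cy, cz = obj.core.center
            lines.append(f"Au {cx:.9g} {cy:.9g} {cz:.9g} "
                         f"{obj.core.radius:.9g} -1")
        chain_of = np.empty(obj.n_beads(), dtype=int)
        for ci, chain in enumerate(obj.chains):
            chain_of[list(chain)] = ci
        for i, (x, y, z) in enumerate(obj.bead_positions):
            lines.append(f"T {x:.9g} {y:.9g} {z:.9g} {bead_radius:.9g} "
                         f"{chain_of[i]}")
    else:
        lines.append(str(len(obj)))
        lines.append(json.dumps({"kind": "body"}))
        for (x, y, z), r in zip(obj.centers, obj.radii):
            lines.append(f"S {x:.9g} {y:.9g} {z:.9g} {r:.9g}")
    path.write_text("\n".join(lines) + "\n")


def read_configuration(path):
    """Read back a configuration/body; raises a parse error that cites the
    offending line number (1-based)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    lines = path.read_text().splitlines()
    try:
        n = int(lines[0])
    except (IndexError, ValueError) as err:
        raise ValueError(f"{path}:1: expected atom count") from err
    try:
        meta = json.loads(lines[1]) if len(lines) > 1 and lines[1].strip() \
            else {}
    except json.JSONDecodeError:
        meta = {}
    rows = []
    for ln in range(2, 2 + n):
        parts = lines[ln].split() if ln < len(lines) else []
        if len(parts) < 5:
            raise ValueError(
                f"{path}:{ln + 1}: need columns 'element x y z radius'"
                + ("" if len(parts) >= 4 else " (radius column missing?)"))
        rows.append(parts)
    if meta.get("kind") == "config":
        core = None
        beads = []
        chain_ids = []
        for parts in rows:
            if parts[0] == "Au":
                core = CoreSpec(radius=float(parts[4]),
                                center=np.array([float(v)
                                                 for v in parts[1:4]]))
            else:
                beads.append([float(v) for v in parts[1:4]])
                chain_ids.append(int(parts[5]))
        chain_ids = np.array(chain_ids)
        chains = [list(np.flatnonzero(chain_ids == c))
                  for c in range(meta["N_c"])]
        anchors = np.array(meta["anchors"]) if "anchors" in meta else None
        return GraftedNPConfig(core=core, chains=chains,
                               anchor_points=anchors,
                               bead_positions=np.array(beads),
                               L=meta["L"], N_c=meta["N_c"])
    centers = np.array([[float(v) for v in parts[1:4]] for parts in rows])
    radii = np.array([float(parts[4]) for parts in rows])
    return SphereUnionBody(centers, radii)


def _write_h5(path, obj, bead_radius):
    import h5py

    with h5py.File(path, "w") as h:
        if isinstance(obj, GraftedNPConfig):
            h.attrs["kind"] = "config"
            h.attrs["L"] = obj.L
            h.attrs["N_c"] = obj.N_c
            h.create_dataset("bead_positions", data=obj.bead_positions)
            h.attrs["bead_radius"] = bead_radius
            if obj.core is not None:
                h.attrs["core_radius"] = obj.core.radius
                h.create_dataset("core_center", data=obj.core.center)
            if obj.anchor_points is not None:
                h.create_dataset("anchors", data=obj.anchor_points)
            h.create_dataset("chains", data=np.array(obj.chains))
        else:
            h.attrs["kind"] = "body"
            h.create_dataset("centers", data=obj.centers)
            h.create_dataset("radii", data=obj.radii)


def _read_h5(path):
    import h5py

    with h5py.File(path, "r") as h:
        if h.attrs["kind"] == "config":
            core = None
            if "core_radius" in h.attrs:
                core = CoreSpec(radius=float(h.attrs["core_radius"]),
                                center=np.array(h["core_center"]))
            anchors = np.array(h["anchors"]) if "anchors" in h else None
            chains = [list(row) for row in np.array(h["chains"])]
            return GraftedNPConfig(core=core, chains=chains,
                                   anchor_points=anchors,
                                   bead_positions=np.array(
                                       h["bead_positions"]),
                                   L=int(h.attrs["L"]),
                                   N_c=int(h.attrs["N_c"]))
        return SphereUnionBody(np.array(h["centers"]), np.array(h["radii"]))


def write_manifest(path, **entries) -> None:
    """Run manifest (parameters, seeds, version, invariant checks) written
    beside outputs."""
    payload = {"package": "graftnp", "version": __version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
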