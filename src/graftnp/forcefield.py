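"""Coarse-grained force field for ssDNA-grafted nanoparticles.

The model is a bead--spring chain in reduced units: every nucleotide is one
bead of diameter ``sigma`` (0.65 nm, the ssDNA base-to-base distance), beads
interact through a shifted-truncated Lennard-Jones potential

    U(r) = U_LJ(r - r_s) - U_LJ(r_c - r_s)   for r < r_c,   0 otherwise,

where the shift ``r_s`` inflates the effective size of a particle (zero for
bead--bead pairs, ``r_s_core`` for the nanoparticle core).  The cutoff
``r_c = r_s + 2^{1/6} sigma`` gives the purely repulsive WCA form;
``r_c = r_s + 2.5 sigma`` adds an attractive well of depth ``eps_s`` used for
the core--bead attraction sweeps.  Consecutive beads are bonded by FENE
springs (Kremer--Grest parameters k = 30/sigma^2, R0 = 1.5 sigma) and chain
stiffness is set by the angular term U_lin(theta) = k_lin (1 + cos theta),
where theta is the interior angle of three consecutive beads (theta = pi is
a straight chain).

Energies are measured in eps_LJ, lengths in nm, temperature in eps_LJ/k_B.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ForceField",
    "CoreSpec",
    "PairClass",
    "pair_energy",
    "pair_force",
    "fene_energy",
    "fene_force",
    "angular_energy",
    "total_energy_forces",
]

WCA_FACTOR = 2.0 ** (1.0 / 6.0)


class PairClass:
    """Pair-interaction classes of the model."""

    BEAD_BEAD = "bead_bead"
    CORE_BEAD = "core_bead"


@dataclass
class ForceField:
    """All potential parameters of the coarse-grained model.

    Parameters
    ----------
    eps_lj : float
        LJ energy scale; defines the energy unit (default 1).
    sigma : float
        Bead diameter in nm (ssDNA base-to-base distance, 0.65 nm).
    r_s_core : float
        Core shift in nm.  The core radius is ``R = r_s_core + sigma/2``;
        the r_s range 0.675-4.675 nm maps to R = 1.0-5.0 nm.
    eps_s : float
        Well depth of the attractive core--bead interaction.  Zero keeps the
        reference (purely repulsive) system.
    core_attractive : bool
        If True (and eps_s > 0) the core--bead pair uses the long cutoff
        ``r_s + 2.5 sigma``; otherwise the WCA cutoff.
    k_fene, r0_fene : float
        FENE spring constant (eps/nm^2) and maximum extension (nm).
    k_lin : float
        Angular stiffness (eps); k_lin = 1 is the ssDNA setting.
    """

    eps_lj: float = 1.0
    sigma: float = 0.65
    r_s_core: float = 4.675
    eps_s: float = 0.0
    core_attractive: bool = False
    k_fene: float = field(default=None)  # type: ignore[assignment]
    r0_fene: float = field(default=None)  # type: ignore[assignment]
    k_lin: float = 1.0

    def __post_init__(self) -> None:
        if self.k_fene is None:
            self.k_fene = 30.0 / self.sigma**2
        if self.r0_fene is None:
            self.r0_fene = 1.5 * self.sigma
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.r0_fene <= self.sigma:
            raise ValueError("FENE maximum extension R0 must exceed sigma")
        if self.eps_lj <= 0:
            raise ValueError("eps_lj must be positive")
        if self.r_s_core < 0 or self.eps_s < 0:
            raise ValueError("r_s_core and eps_s must be non-negative")

    # -- pair-class geometry ------------------------------------------------
    def r_shift(self, pair_class: str) -> float:
        return self.r_s_core if pair_class == PairClass.CORE_BEAD else 0.0

    def is_attractive(self, pair_class: str) -> bool:
        return (
            pair_class == PairClass.CORE_BEAD
            and self.core_attractive
            and self.eps_s > 0
        )

    def pair_eps(self, pair_class: str) -> float:
        return self.eps_s if self.is_attractive(pair_class) else self.eps_lj

    def cutoff(self, pair_class: str) -> float:
        rs = self.r_shift(pair_class)
        if self.is_attractive(pair_class):
            return rs + 2.5 * self.sigma
        return rs + WCA_FACTOR * self.sigma

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(**d)


@dataclass
class CoreSpec:
    """Spherical nanoparticle core: radius R = r_s_core + sigma/2, in nm."""

    radius: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("core radius must be positive")

    @classmethod
    def from_forcefield(cls, ff: ForceField) -> "CoreSpec":
        return cls(radius=ff.r_s_core + ff.sigma / 2.0)


def _lj(u: np.ndarray, eps: float, sigma: float) -> np.ndarray:
    s6 = (sigma / u) ** 6
    return 4.0 * eps * (s6 * s6 - s6)


def pair_energy(r, pair_class: str, ff: ForceField):
    """Shifted-truncated LJ pair energy at center distance ``r`` (nm).

    Exactly zero for r >= r_c and continuous there.  Raises for r <= r_s
    (the configuration has penetrated the shifted core and is unphysical).
    """
    r = np.asarray(r, dtype=float)
    rs = ff.r_shift(pair_class)
    if np.any(r <= rs):
        raise ValueError(
            f"pair distance {r} below shift r_s={rs} for class {pair_class}: "
            "unphysical configuration"
        )
    rc = ff.cutoff(pair_class)
    eps = ff.pair_eps(pair_class)
    u = np.minimum(r - rs, rc - rs)
    e = _lj(u, eps, ff.sigma) - _lj(np.asarray(rc - rs), eps, ff.sigma)
    return np.where(r >= rc, 0.0, e)[()]


def pair_force(r, pair_class: str, ff: ForceField):
    """Magnitude of the radial pair force, -dU/dr (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    rs = ff.r_shift(pair_class)
    if np.any(r <= rs):
        raise ValueError("pair distance below shift r_s")
    rc = ff.cutoff(pair_class)
    eps = ff.pair_eps(pair_class)
    u = r - rs
    s6 = (ff.sigma / u) ** 6
    f = 24.0 * eps * (2.0 * s6 * s6 - s6) / u
    return np.where(r >= rc, 0.0, f)[()]


def fene_energy(r, ff: ForceField):
    """FENE bond energy -(1/2) k R0^2 ln(1 - (r/R0)^2); diverges at R0."""
    r = np.asarray(r, dtype=float)
    r0 = ff.r0_fene
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= r0):
        raise ValueError(
            f"bond length {r} >= R0={r0}: broken bond "
            "(integrator time step too large)"
        )
    return (-0.5 * ff.k_fene * r0**2 * np.log1p(-((r / r0) ** 2)))[()]


def fene_force(r, ff: ForceField):
    """FENE restoring force magnitude k r / (1 - (r/R0)^2)."""
    r = np.asarray(r, dtype=float)
    r0 = ff.r0_fene
    if np.any(r >= r0):
        raise ValueError("broken bond")
    return (ff.k_fene * r / (1.0 - (r / r0) ** 2))[()]


def angular_energy(theta, ff: ForceField):
    """Stiffness energy k_lin (1 + cos theta); zero for a straight chain."""
    ct = np.clip(np.cos(np.asarray(theta, dtype=float)), -1.0, 1.0)
    return (ff.k_lin * (1.0 + ct))[()]


def _angle_forces(ri, rj, rk, k_lin):
    """Forces of U = k(1 + cos theta), theta the interior angle at rj."""
    a = ri - rj
    b = rk - rj
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    ct = float(a @ b) / (na * nb)
    ga = (b / nb - ct * a / na) / na  # d cos(theta) / d ri
    gb = (a / na - ct * b / nb) / nb  # d cos(theta) / d rk
    fi = -k_lin * ga
    fk = -k_lin * gb
    return fi, -(fi + fk), fk, k_lin * (1.0 + ct)


def total_energy_forces(config, ff: ForceField):
    """Total potential energy and per-bead forces of a configuration.

    Sums the bead--bead WCA term over all pairs (bonded pairs included, the
    standard bead--spring convention), the core--bead shifted LJ, FENE bonds
    along each chain plus the tether bond to the fixed anchor point, and the
    angular term at every interior bead.  Forces are the exact negative
    gradient; the reaction on the immobile core balances the core--bead
    forces.

    Returns ``(energy, forces, core_reaction)``.
    """
    x = np.asarray(config.bead_positions, dtype=float)
    n = len(x)
    f = np.zeros((n, 3))
    e = 0.0

    # bead-bead WCA over all pairs
    if n > 1:
        d = x[:, None, :] - x[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        rr = r[iu, ju]
        if np.any(rr <= 0):
            raise ValueError("coincident beads")
        e += float(np.sum(pair_energy(rr, PairClass.BEAD_BEAD, ff)))
        fm = pair_force(rr, PairClass.BEAD_BEAD, ff)  # -dU/dr
        # force on i along (ri - rj)
        fv = (fm / rr)[:, None] * d[iu, ju]
        np.add.at(f, iu, fv)
        np.add.at(f, ju, -fv)

    # core-bead
    core_reaction = np.zeros(3)
    if n > 0 and config.core is not None:
        dc = x - config.core.center
        rc = np.linalg.norm(dc, axis=1)
        e += float(np.sum(pair_energy(rc, PairClass.CORE_BEAD, ff)))
        fm = pair_force(rc, PairClass.CORE_BEAD, ff)
        fv = (fm / rc)[:, None] * dc
        f += fv
        core_reaction = -fv.sum(axis=0)

    # bonds (FENE): consecutive beads and the tether to the anchor point
    for ci, chain in enumerate(config.chains):
        idx = list(chain)
        if config.anchor_points is not None and config.core is not None:
            anchor = (
                config.core.center
                + config.core.radius * np.asarray(config.anchor_points[ci])
            )
            dv = x[idx[0]] - anchor
            rb = np.linalg.norm(dv)
            try:
                e += float(fene_energy(rb, ff))
            except ValueError as err:
                raise ValueError(f"tether bond of chain {ci}: {err}") from err
            fb = -fene_force(rb, ff) / rb * dv
            f[idx[0]] += fb
            core_reaction -= fb
        for a, b in zip(idx[:-1], idx[1:]):
            dv = x[b] - x[a]
            rb = np.linalg.norm(dv)
            try:
                e += float(fene_energy(rb, ff))
            except ValueError as err:
                raise ValueError(f"bond {a}-{b}: {err}") from err
            fb = fene_force(rb, ff) / rb * dv
            f[a] += fb
            f[b] -= fb
        # angular terms at interior beads (none at the tether anchor)
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            fi, fj, fk, ea = _angle_forces(x[a], x[b], x[c], ff.k_lin)
            e += ea
            f[a] += fi
            f[b] += fj
            f[c] += fk

    return e, f, core_reaction
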