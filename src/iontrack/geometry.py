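"""Irradiation geometry and dose/fluence/LET scoring.

The target is a spherical cell nucleus (default 10 um diameter) centred
at the origin.  A circular ion source disc (default 80 um^2) lies
tangential to the nucleus; per run, a fixed number of primaries
(default 5, i.e. fluence 0.0625 um^-2) start exactly parallel from
random positions on the disc, perpendicular to it.  Interactions are
scored inside a concentric sphere of 14.22 um diameter which always
contains the rotated source area.

Simulation runs work in the *beam frame*: the source disc is the plane
z = -R_nucleus and ions travel along +z.  The per-run random rotation
of the source relative to the chromatin model is carried by
:class:`RunFrame` and applied to the genome model instead (statistically
equivalent for a spherical nucleus and much cheaper).

LET is obtained from dose and fluence via
``D [Gy] = 0.1602 * LET [keV/um] * phi [um^-2]`` (unit conversion at
liquid-water density).  For stoppers, the dose-averaging volume is the
spherical cap whose height is the ion's range; local LET uses a stack
of 200 nm slabs perpendicular to the beam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barkas import IonSpec
from .constants import EV_TO_J, KG_PER_UM3, LET_COEFF
from .transport import Deposits, IonState

__all__ = [
    "NucleusGeometry",
    "RunFrame",
    "random_rotation",
    "make_run",
    "dose",
    "dose_in_nucleus",
    "let_from_dose_fluence",
    "dose_from_let_fluence",
    "cap_volume",
    "slab_profile",
    "sphere_slab_volume",
]


@dataclass(frozen=True)
class NucleusGeometry:
    """Spherical nucleus + tangential disc source + slab stack."""

    nucleus_diameter: float = 10.0       # um
    scoring_diameter: float = 14.22      # um
    source_area: float = 80.0            # um^2
    primaries_per_run: int = 5
    slab_thickness: float = 0.2          # um
    n_slabs: int = 50

    def __post_init__(self) -> None:
        if self.scoring_diameter <= self.nucleus_diameter:
            raise ValueError("scoring sphere must enclose the nucleus")
        if self.primaries_per_run < 1 or self.source_area <= 0:
            raise ValueError("need >= 1 primary and positive source area")

    @property
    def nucleus_radius(self) -> float:
        return self.nucleus_diameter / 2.0

    @property
    def scoring_radius(self) -> float:
        return self.scoring_diameter / 2.0

    @property
    def source_radius(self) -> float:
        return float(np.sqrt(self.source_area / np.pi))

    @property
    def fluence(self) -> float:
        """Planar fluence per run (um^-2)."""
        return self.primaries_per_run / self.source_area

    @property
    def nucleus_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.nucleus_radius**3


@dataclass
class RunFrame:
    """Per-run random orientation of the source relative to the chromatin.

    ``rotation`` maps chromatin-model coordinates into the beam frame;
    beam-frame deposit positions map into the model frame through its
    transpose.  Proper rotation: orthonormal, determinant +1.
    """

    rotation: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        self.rotation = r

    def to_model_frame(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation  # == (R.T @ p.T).T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (random unit quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_run(
    geometry: NucleusGeometry,
    ion: IonSpec,
    energy_mev_u: float,
    rng: np.random.Generator,
    seed: int = 0,
) -> tuple[RunFrame, list[IonState]]:
    """Draw one run: a random source orientation and the primary ions.

    Ions start from uniform random positions on the source disc (plane
    z = -R_nucleus in the beam frame), all travelling along +z.
    """
    frame = RunFrame(rotation=random_rotation(rng), seed=seed)
    r = geometry.source_radius * np.sqrt(rng.random(geometry.primaries_per_run))
    phi = rng.uniform(0.0, 2.0 * np.pi, geometry.primaries_per_run)
    z0 = -geometry.nucleus_radius
    states = [
        IonState(ion, energy_mev_u,
                 np.array([ri * np.cos(p), ri * np.sin(p), z0]),
                 np.array([0.0, 0.0, 1.0]))
        for ri, p in zip(r, phi)
    ]
    return frame, states


# -- dose and LET -----------------------------------------------------------

def dose(deposits: Deposits, region_volume_um3: float,
         region_predicate) -> float:
    """Dose (Gy) from deposits inside a region of given volume.

    ``region_predicate`` maps an (n, 3) position array to a boolean
    mask.  Empty regions give zero dose.
    """
    if region_volume_um3 <= 0:
        raise ValueError("region volume must be positive")
    if len(deposits) == 0:
        return 0.0
    mask = np.asarray(region_predicate(deposits.position), dtype=bool)
    e_ev = float(deposits.energy[mask].sum())
    return e_ev * EV_TO_J / (region_volume_um3 * KG_PER_UM3)


def dose_in_nucleus(deposits: Deposits, geometry: NucleusGeometry,
                    cap_height_um: float | None = None) -> float:
    """Nucleus dose; for stoppers, averaged over the entrance spherical cap.

    ``cap_height_um`` is the ion range for stoppers (range < nucleus
    diameter); the cap grows from the beam entrance plane z = -R.
    """
    r = geometry.nucleus_radius
    if cap_height_um is None or cap_height_um >= geometry.nucleus_diameter:
        vol = geometry.nucleus_volume
        z_max = r
    else:
        vol = cap_volume(geometry, cap_height_um)
        z_max = -r + cap_height_um

    def pred(p):
        inside = np.einsum("ij,ij->i", p, p) <= r**2
        return inside & (p[:, 2] <= z_max)

    return dose(deposits, vol, pred)


def let_from_dose_fluence(dose_gy: float, fluence_per_um2: float) -> float:
    """LET (keV/um) from dose (Gy) and fluence (um^-2)."""
    if fluence_per_um2 <= 0:
        raise ValueError("fluence must be positive")
    return dose_gy / (LET_COEFF * fluence_per_um2)


def dose_from_let_fluence(let_kev_um: float, fluence_per_um2: float) -> float:
    """Inverse of :func:`let_from_dose_fluence`."""
    return LET_COEFF * let_kev_um * fluence_per_um2


def cap_volume(geometry: NucleusGeometry, range_um: float) -> float:
    """Volume (um^3) of the spherical cap of height = ion range.

    Full sphere volume once the range reaches the nucleus diameter.
    """
    if range_um <= 0:
        raise ValueError("range must be positive")
    d = geometry.nucleus_diameter
    r = geometry.nucleus_radius
    if range_um >= d:
        return geometry.nucleus_volume
    h = range_um
    return np.pi * h**2 * (3.0 * r - h) / 3.0


def sphere_slab_volume(radius: float, z_lo: float, z_hi: float) -> float:
    """Volume of the intersection of a sphere |x| <= radius with a slab."""
    a = np.clip(z_lo, -radius, radius)
    b = np.clip(z_hi, -radius, radius)
    if b <= a:
        return 0.0
    prim = lambda z: radius**2 * z - z**3 / 3.0
    return float(np.pi * (prim(b) - prim(a)))


def slab_profile(deposits: Deposits, geometry: NucleusGeometry,
                 fluence_per_um2: float | None = None) -> pd.DataFrame:
    """Per-slab dose and local LET through the nucleus.

    Slabs are perpendicular to the beam axis, starting at the source
    plane (z = -R_nucleus).  Per-slab dose relates the energy deposited
    in slab-inside-nucleus to that intersection volume; per-slab LET
    follows from the run fluence.  Sums of per-slab energy close on the
    total in-nucleus energy.
    """
    if fluence_per_um2 is None:
        fluence_per_um2 = geometry.fluence
    r = geometry.nucleus_radius
    n = geometry.n_slabs
    dz = geometry.slab_thickness
    edges = -r + dz * np.arange(n + 1)
    if len(deposits):
        p = deposits.position
        in_nuc = np.einsum("ij,ij->i", p, p) <= r**2
        z = p[in_nuc, 2]
        e = deposits.energy[in_nuc]
        idx = np.clip(((z + r) / dz).astype(int), 0, n - 1)
        energy = np.bincount(idx, weights=e, minlength=n)
    else:
        energy = np.zeros(n)
    vols = np.array([sphere_slab_volume(r, edges[i], edges[i + 1])
                     for i in range(n)])
    with np.errstate(divide="ignore", invalid="ignore"):
        dose_gy = np.where(vols > 0,
                           energy * EV_TO_J / (vols * KG_PER_UM3), 0.0)
    let = dose_gy / (LET_COEFF * fluence_per_um2)
    return pd.DataFrame({
        "depth_um": 0.5 * (edges[:-1] + edges[1:]) + r,
        "energy_eV": energy,
        "volume_um3": vols,
        "dose_Gy": dose_gy,
        "let_keV_um": let,
    })
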