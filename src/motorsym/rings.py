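"""Closed protomer rings: bending, stoichiometry, registration, fit scoring.

Geometry of the concentric-ring disk model: a linear oligomer repeat with
lateral rise w bent onto a closed arc of n protomers sits at radius
r = n*w/(2*pi); rings at larger radii incorporate more protomers in
proportion to their circumference.  Symmetry-mismatch registration between
a ring of n protomers and a scaffold of s units is plain gcd arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fourier import FSC_MAP_MODEL, fsc, resolution_at
from .models import PseudoAtomModel, rasterize
from .volume import Volume


@dataclass
class LatticeTransform:
    """Repeat geometry of the unbent linear oligomer.

    rise : lateral translation per protomer along the oligomer axis, Å
    twist : relative rotation between successive protomers, radians
    """

    rise: float
    twist: float = 0.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError(f"rise must be > 0, got {self.rise}")


def bend_to_arc(protomer: PseudoAtomModel, t: LatticeTransform, n: int,
                z_center: float = 0.0) -> PseudoAtomModel:
    """Bend n rigid protomer repeats onto a closed ring.

    The ring radius is r = n * rise / (2*pi), so neighbouring protomer
    centres are separated by the chord 2 r sin(pi/n), which approaches the
    linear rise as n grows.  Protomer k is protomer 0 rotated rigidly by
    2*pi*k/n about the ring axis (plus k*twist about the local tangent);
    the ring closes exactly because protomer n coincides with protomer 0
    whenever n*twist is a multiple of 2*pi.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 protomers to close an arc, got {n}")
    r = n * t.rise / (2.0 * np.pi)
    parts = []
    for k in range(n):
        theta = 2.0 * np.pi * k / n
        c, s = np.cos(theta), np.sin(theta)
        ring_rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        tw = k * t.twist
        ct, st = np.cos(tw), np.sin(tw)
        # twist about the local tangent (local y before ring rotation)
        twist_rot = np.array([[ct, 0.0, -st], [0.0, 1.0, 0.0], [st, 0.0, ct]])
        placed = protomer.transformed(
            ring_rot @ twist_rot, ring_rot @ np.array([r, 0.0, z_center])
        )
        placed.chains = [f"p{k}"] * len(placed)
        parts.append(placed)
    return PseudoAtomModel.concatenate(parts)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def predict_ring_counts(
    n1: int, r1: float, radii: list[float], tie_tol: float = 0.05
) -> tuple[list[int], list[int]]:
    """Protomer counts of concentric rings from circumference ratios.

    The first ring fixes the protomer arc width w = 2*pi*r1/n1; ring k
    carries round(2*pi*r_k/w) protomers (round half away from zero;
    near-half cases within ``tie_tol`` of .5 are flagged with a warning so
    rounding-model ties stay visible).  Returns (counts, increments).
    """
    if n1 < 1:
        raise ValueError(f"n1 must be >= 1, got {n1}")
    if r1 <= 0:
        raise ValueError(f"r1 must be > 0, got {r1}")
    radii = list(radii)
    if not radii or abs(radii[0] - r1) > 1e-9:
        raise ValueError("radii must start at r1")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    w = 2.0 * np.pi * r1 / n1
    counts = []
    for rk in radii:
        x = 2.0 * np.pi * rk / w
        frac = abs(x - math.floor(x) - 0.5)
        if frac < tie_tol:
            warnings.warn(
                f"ring at r={rk:.2f} Å has near-half protomer count {x:.3f}; "
                "rounded half away from zero",
                stacklevel=2,
            )
        counts.append(_round_half_away(x))
    increments = [b - a for a, b in zip(counts, counts[1:])]
    return counts, increments


def ring_from_asymmetric_unit(units: int, protomers_per_unit: int) -> int:
    """Total ring protomers from repeating asymmetric units (e.g. 17 trimers -> 51)."""
    if units < 1 or protomers_per_unit < 1:
        raise ValueError("units and protomers_per_unit must be >= 1")
    return units * protomers_per_unit


@dataclass
class RegistrationResult:
    """Symmetry-mismatch registration of a ring against a scaffold.

    period : ring protomers per scaffold contact (every ``period``-th ring
        protomer is contacted)
    contacts : number of ring protomers contacted = gcd(n_ring, n_scaffold)
    offset_angle : azimuthal offset of the contact lattice, radians (0 for
        phase-aligned lattices)
    incommensurate : True when gcd = 1 for a multi-unit scaffold, i.e. no
        repeating contact pattern exists
    """

    period: int
    contacts: int
    offset_angle: float = 0.0
    incommensurate: bool = False


def register(n_ring: int, n_scaffold: int) -> RegistrationResult:
    """Contact arithmetic between an n-fold ring and an s-fold scaffold.

    A 51-protomer ring against a C17 scaffold gives period 3 (each third
    ring protomer contacted) and 17 contacts; a 26-fold ring against C17
    is incommensurate (gcd 1).
    """
    if n_ring < 1 or n_scaffold < 1:
        raise ValueError("n_ring and n_scaffold must be >= 1")
    g = math.gcd(n_ring, n_scaffold)
    period = n_ring // g
    return RegistrationResult(
        period=period,
        contacts=g,
        offset_angle=0.0,
        incommensurate=(g == 1 and n_scaffold > 1),
    )


def soft_spherical_mask(
    n: int, voxel_size: float, center: np.ndarray, radius: float, soft_edge: float
) -> np.ndarray:
    """1 inside ``radius``, raised-cosine falloff over ``soft_edge`` Å."""
    ax = (np.arange(n) - n / 2.0) * voxel_size
    d = np.sqrt(
        (ax[:, None, None] - center[0]) ** 2
        + (ax[None, :, None] - center[1]) ** 2
        + (ax[None, None, :] - center[2]) ** 2
    )
    t = np.clip((d - radius) / soft_edge, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def score_ring_fit(model: PseudoAtomModel, target: Volume,
                   soft_edge: float = 12.0) -> float:
    """Map-model resolution (Å) at FSC = 0.5 for a ring model in a map.

    The model is rasterized on the target grid, a soft spherical mask
    enclosing the model (its centroid-to-blob extent plus 3 sigma, cosine
    edge) is applied to both maps, and the first FSC = 0.5 crossing is
    reported.  A curve that never drops below 0.5 scores at the Nyquist
    resolution 2 * voxel (the best resolvable value).
    """
    raster = rasterize(model, target.n, target.voxel_size)
    if not np.any(raster.grid > 0):
        raise ValueError("model and target volume do not overlap")
    centre = model.centroid()
    extent = float(
        np.max(np.linalg.norm(model.positions - centre, axis=1) + 3.0 * model.sigmas)
    )
    if extent + soft_edge >= target.extent * np.sqrt(3.0):
        raise ValueError("model does not fit inside the target box")
    mask = soft_spherical_mask(target.n, target.voxel_size, centre, extent, soft_edge)
    a = Volume(raster.grid * mask, target.voxel_size)
    b = Volume(target.grid * mask, target.voxel_size)
    res = resolution_at(fsc(a, b), FSC_MAP_MODEL)
    return 2.0 * target.voxel_size if res is None else res
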