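"""Synthetic motor-like density phantoms.

Generates volumes with the geometric structure the analysis stages assume:
coaxial components of distinct cyclic symmetries (a C17 periplasmic
scaffold, a C38 C-ring, a C26 LP-ring, an azimuthally featureless rod) and
concentric protomer disks, with additive Gaussian noise and an optional
tomographic missing wedge.

All generators are pure functions of their specs, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import PseudoAtomModel, ProtomerShape, default_protomer, post_protomer, rasterize
from .volume import Volume


@dataclass
class RingLatticeSpec:
    """Geometry of one closed ring of protomers.

    n_protomers protomer centres equally spaced on a circle of ``radius`` Å
    at height ``z_center`` Å, first protomer at azimuth ``phase``; ``tilt``
    rotates the protomer frame about the local tangent.
    """

    n_protomers: int
    radius: float
    z_center: float = 0.0
    phase: float = 0.0
    tilt: float = 0.0

    def __post_init__(self) -> None:
        if self.n_protomers < 1:
            raise ValueError(f"n_protomers must be >= 1, got {self.n_protomers}")
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        self.phase = float(self.phase) % (2.0 * np.pi)


@dataclass
class DiskSpec:
    """A stack of concentric rings sharing one protomer arc width.

    ``protomer_arc_width`` (w, Å) is the arc length one protomer occupies on
    its ring circumference; ``ring_spacing`` (Δr, Å) the radial pitch.
    """

    rings: list[RingLatticeSpec]
    protomer_arc_width: float
    ring_spacing: float

    def __post_init__(self) -> None:
        if self.protomer_arc_width <= 0:
            raise ValueError(
                f"protomer_arc_width must be > 0, got {self.protomer_arc_width}"
            )
        radii = [r.radius for r in self.rings]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("ring radii must be strictly increasing")


def build_disk_spec(
    n1: int, r1: float, n_rings: int, ring_spacing: float, z_center: float = 0.0
) -> DiskSpec:
    """Concentric-ring disk from a first ring and the circumference model.

    The first ring carries ``n1`` protomers at radius ``r1``, fixing the
    protomer arc width w = 2*pi*r1/n1.  Ring k (1-based) sits at
    ``r1 + (k-1)*ring_spacing`` and carries ``round(2*pi*r_k / w)``
    protomers (round half away from zero).
    """
    if n1 < 1:
        raise ValueError(f"n1 must be >= 1, got {n1}")
    if r1 <= 0:
        raise ValueError(f"r1 must be > 0, got {r1}")
    if n_rings < 1:
        raise ValueError(f"n_rings must be >= 1, got {n_rings}")
    if ring_spacing <= 0:
        raise ValueError(f"ring_spacing must be > 0, got {ring_spacing}")
    w = 2.0 * np.pi * r1 / n1
    rings = []
    for k in range(n_rings):
        rk = r1 + k * ring_spacing
        nk = int(np.floor(2.0 * np.pi * rk / w + 0.5))
        rings.append(RingLatticeSpec(n_protomers=nk, radius=rk, z_center=z_center))
    return DiskSpec(rings=rings, protomer_arc_width=w, ring_spacing=ring_spacing)


@dataclass
class RingComponent:
    """A single protomer ring plus the shape to place on it."""

    ring: RingLatticeSpec
    protomer: ProtomerShape = field(default_factory=default_protomer)
    name: str = "ring"


@dataclass
class DiskComponent:
    """A concentric-ring disk plus the shape to place on each ring."""

    disk: DiskSpec
    protomer: ProtomerShape = field(default_factory=default_protomer)
    name: str = "disk"


@dataclass
class TubeComponent:
    """An azimuthally featureless (lathed) annular tube.

    Density ``amplitude * exp(-(r-radius)^2 / 2 wall_sigma^2)`` over an
    axial slab of the given height, with half-Gaussian rolloff at the ends.
    """

    radius: float
    z_center: float
    height: float
    wall_sigma: float = 4.0
    amplitude: float = 1.0
    name: str = "tube"

    def __post_init__(self) -> None:
        if self.radius < 0 or self.height <= 0 or self.wall_sigma <= 0:
            raise ValueError(f"invalid tube geometry in component '{self.name}'")


PhantomComponent = RingComponent | DiskComponent | TubeComponent


@dataclass
class MotorPhantomSpec:
    """Full phantom recipe: components, box, noise and missing wedge."""

    components: list[PhantomComponent]
    box_size: int = 192
    voxel_size: float = 2.0
    noise_sd: float = 0.0
    missing_wedge_half_angle: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_size % 2 != 0:
            raise ValueError(f"box_size must be even, got {self.box_size}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def ring_model(ring: RingLatticeSpec, protomer: ProtomerShape) -> PseudoAtomModel:
    """Place a protomer shape on every site of a ring lattice.

    Protomer frame: local x -> radially outward, local y -> tangential
    (CCW), local z -> axial; ``tilt`` rotates that frame about the tangent.
    Each protomer is one chain.
    """
    base = PseudoAtomModel.from_protomer(protomer)
    ct, st = np.cos(ring.tilt), np.sin(ring.tilt)
    # tilt about local y (tangent): x' = x cos - z sin, z' = x sin + z cos
    tilt_mat = np.array([[ct, 0.0, -st], [0.0, 1.0, 0.0], [st, 0.0, ct]])
    parts = []
    for k in range(ring.n_protomers):
        theta = ring.phase + 2.0 * np.pi * k / ring.n_protomers
        c, s = np.cos(theta), np.sin(theta)
        frame = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]) @ tilt_mat
        centre = np.array([ring.radius * c, ring.radius * s, ring.z_center])
        placed = base.transformed(frame, centre)
        placed.chains = [f"{protomer.label}_{k}"] * len(placed)
        parts.append(placed)
    return PseudoAtomModel.concatenate(parts)


def disk_model(disk: DiskSpec, protomer: ProtomerShape) -> PseudoAtomModel:
    parts = [ring_model(r, protomer) for r in disk.rings]
    for i, p in enumerate(parts):
        p.chains = [f"r{i + 1}_{c}" for c in p.chains]
    return PseudoAtomModel.concatenate(parts)


def _tube_density(comp: TubeComponent, box_size: int, voxel_size: float) -> np.ndarray:
    n = box_size
    ax = (np.arange(n) - n / 2.0) * voxel_size
    r = np.hypot(ax[:, None], ax[None, :])
    radial = comp.amplitude * np.exp(-((r - comp.radius) ** 2) / (2 * comp.wall_sigma**2))
    dz = np.abs(ax - comp.z_center) - comp.height / 2.0
    axial = np.where(dz <= 0, 1.0, np.exp(-(dz**2) / (2 * comp.wall_sigma**2)))
    return radial[:, :, None] * axial[None, None, :]


def _component_max_radius(comp: PhantomComponent) -> float:
    if isinstance(comp, TubeComponent):
        return comp.radius + 4.0 * comp.wall_sigma
    if isinstance(comp, RingComponent):
        return ring_model(
            RingLatticeSpec(1, comp.ring.radius, comp.ring.z_center, tilt=comp.ring.tilt),
            comp.protomer,
        ).max_radius()
    outer = comp.disk.rings[-1]
    return ring_model(
        RingLatticeSpec(1, outer.radius, outer.z_center), comp.protomer
    ).max_radius()


def apply_missing_wedge(v: Volume, half_angle_deg: float) -> Volume:
    """Zero Fourier coefficients inside the tomographic missing wedge.

    Tilt axis y, beam axis z: the double wedge of directions within
    ``half_angle_deg`` of the k_z axis in the (k_x, k_z) plane is unsampled
    by a limited tilt series (half-angle 33 deg corresponds to a +/-57 deg
    tilt range).
    """
    n = v.n
    f = np.fft.fftn(v.grid)
    k = np.fft.fftfreq(n)
    kx = np.abs(k)[:, None, None]
    kz = np.abs(k)[None, None, :]
    tan_half = np.tan(np.deg2rad(half_angle_deg))
    # strict inequality: the kz = 0 plane (including DC) is always sampled
    wedge = kx < kz * tan_half
    f = np.where(wedge, 0.0, f)
    return Volume(np.fft.ifftn(f).real, v.voxel_size, v.origin)


def make_motor_phantom(spec: MotorPhantomSpec) -> Volume:
    """Build the phantom volume: components + Gaussian noise (+ wedge).

    Deterministic given the spec (including seed).  Components whose
    density would overlap the box edge are rejected with an error naming
    the offending component.
    """
    half = spec.box_size * spec.voxel_size / 2.0
    for i, comp in enumerate(spec.components):
        if _component_max_radius(comp) >= half - spec.voxel_size:
            name = getattr(comp, "name", f"component {i}")
            raise ValueError(
                f"component '{name}' (index {i}) overlaps the box edge: "
                f"max radius {_component_max_radius(comp):.1f} Å vs half-box {half:.1f} Å"
            )
    grid = np.zeros((spec.box_size,) * 3)
    for comp in spec.components:
        if isinstance(comp, TubeComponent):
            grid += _tube_density(comp, spec.box_size, spec.voxel_size)
        elif isinstance(comp, RingComponent):
            grid += rasterize(
                ring_model(comp.ring, comp.protomer), spec.box_size, spec.voxel_size
            ).grid
        else:
            grid += rasterize(
                disk_model(comp.disk, comp.protomer), spec.box_size, spec.voxel_size
            ).grid
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grid = grid + rng.normal(0.0, spec.noise_sd, grid.shape)
    vol = Volume(grid, spec.voxel_size)
    if spec.missing_wedge_half_angle is not None:
        vol = apply_missing_wedge(vol, spec.missing_wedge_half_angle)
    return vol


def signal_rms(clean: Volume) -> float:
    """RMS density of a clean map over the whole box.

    Converts a requested SNR into an additive noise sd under the usual
    whole-map variance-ratio convention: SNR = map RMS / noise sd.
    """
    rms = float(np.sqrt(np.mean(clean.grid**2)))
    if rms == 0:
        raise ValueError("clean phantom has no signal")
    return rms


@dataclass(frozen=True)
class Annulus:
    """Cylindrical analysis region: radii and z in Å, box-centre relative."""

    r_min: float
    r_max: float
    z_min: float
    z_max: float


# Standard phantom geometry (Å).  Radii and heights are compressed so the
# whole symmetry-mismatched stack fits a 192^3 box at 2 Å/voxel; only the
# cyclic orders and the separability of the annuli matter downstream.
SCAFFOLD_RING = RingLatticeSpec(n_protomers=17, radius=120.0, z_center=30.0)
CRING_RING = RingLatticeSpec(n_protomers=38, radius=150.0, z_center=-80.0)
LPRING_RING = RingLatticeSpec(n_protomers=26, radius=80.0, z_center=70.0)
ROD_TUBE = TubeComponent(radius=25.0, z_center=0.0, height=200.0, wall_sigma=4.0,
                         amplitude=0.8, name="rod")

STANDARD_ANNULI: dict[str, Annulus] = {
    "scaffold": Annulus(100.0, 140.0, 10.0, 50.0),
    "cring": Annulus(130.0, 172.0, -100.0, -60.0),
    "lpring": Annulus(60.0, 100.0, 50.0, 90.0),
}


def standard_phantom_spec(
    seed: int = 20231009,
    snr: float = 0.5,
    box_size: int = 192,
    voxel_size: float = 2.0,
    missing_wedge_half_angle: float | None = None,
) -> MotorPhantomSpec:
    """Spec for the standard multi-symmetry motor phantom.

    ``snr`` is the clean-map RMS divided by the additive noise sd (the
    whole-map variance-ratio convention); ``snr=None`` or 0 gives a
    noise-free phantom.
    """
    components: list[PhantomComponent] = [
        RingComponent(SCAFFOLD_RING, default_protomer("scaffold"), name="scaffold"),
        RingComponent(CRING_RING, post_protomer("cring"), name="cring"),
        RingComponent(LPRING_RING, default_protomer("lpring"), name="lpring"),
        ROD_TUBE,
    ]
    spec = MotorPhantomSpec(
        components=components,
        box_size=box_size,
        voxel_size=voxel_size,
        noise_sd=0.0,
        missing_wedge_half_angle=missing_wedge_half_angle,
        seed=seed,
    )
    if snr:
        clean = make_motor_phantom(replace(spec, noise_sd=0.0, missing_wedge_half_angle=None))
        spec = replace(spec, noise_sd=signal_rms(clean) / snr)
    return spec


def make_standard_phantom(
    seed: int = 20231009, snr: float = 0.5, box_size: int = 192, voxel_size: float = 2.0
) -> tuple[Volume, dict[str, Annulus]]:
    """The standard phantom volume plus its named analysis annuli."""
    spec = standard_phantom_spec(seed=seed, snr=snr, box_size=box_size, voxel_size=voxel_size)
    return make_motor_phantom(spec), dict(STANDARD_ANNULI)


def collar_phantom(
    radius: float,
    seed: int = 20231009,
    snr: float = 1.0,
    box_size: int = 96,
    voxel_size: float = 2.0,
    height: float = 60.0,
    wall_sigma: float = 4.0,
) -> Volume:
    """Beta-collar-like tube phantom with its wall centred at ``radius`` Å."""
    tube = TubeComponent(radius=radius, z_center=0.0, height=height,
                         wall_sigma=wall_sigma, name="collar")
    spec = MotorPhantomSpec([tube], box_size=box_size, voxel_size=voxel_size, seed=seed)
    if snr:
        clean = make_motor_phantom(spec)
        spec = replace(spec, noise_sd=signal_rms(clean) / snr)
    return make_motor_phantom(spec)
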