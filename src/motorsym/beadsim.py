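"""Simulated tethered-bead trajectories of a stepping rotary motor.

The motor hops unidirectionally (CCW; the assayed strain carries a cheY
deletion, so the motor never switches) among N equally spaced dwell
angles with exponential dwell times.  De-energization (CCCP) is modelled
purely as a dwell-rate multiplier.  The bead reports the motor angle
through an elastic linkage (Gaussian angular noise) and projects onto an
ellipse in the image plane with Gaussian localization noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EllipseSpec:
    """Projected bead orbit: semi-axes, centre and orientation (radians)."""

    semi_major: float = 250.0
    semi_minor: float = 200.0
    center: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.3

    def __post_init__(self) -> None:
        if self.semi_major <= 0 or self.semi_minor <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.semi_minor > self.semi_major:
            raise ValueError("semi_major must be >= semi_minor")


@dataclass
class BeadSimSpec:
    """Stepping-bead simulation parameters.

    Defaults emulate a 1.3 µm bead on a CCCP-slowed motor: 26 dwell
    positions, 10 ms mean dwell at full energization, 0.04 rad elastic
    linkage noise, 10 nm localization noise on a 250 x 200 nm orbit,
    sampled at 1 kHz for 20 s (about 77 revolutions).
    """

    n_dwells: int = 26
    mean_dwell_time: float = 0.01
    linkage_sd: float = 0.04
    localization_sd: float = 10.0
    ellipse: EllipseSpec = field(default_factory=EllipseSpec)
    sample_rate: float = 1000.0
    duration: float = 20.0
    deenergization_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dwells < 2:
            raise ValueError(f"n_dwells must be >= 2, got {self.n_dwells}")
        for name in ("mean_dwell_time", "sample_rate", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.linkage_sd < 0 or self.localization_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not (0.0 < self.deenergization_factor <= 1.0):
            raise ValueError("deenergization_factor must be in (0, 1]")


@dataclass
class BeadTrajectory:
    """Time-stamped bead positions, uniform sampling, one condition."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.time) == len(self.x) == len(self.y)):
            raise ValueError("time, x, y must have equal length")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be strictly increasing and uniform")

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"time_s": self.time, "x": self.x, "y": self.y}).to_csv(
            path, index=False
        )

    @staticmethod
    def from_csv(path: str, condition: str = "") -> "BeadTrajectory":
        df = pd.read_csv(path)
        return BeadTrajectory(
            df["time_s"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), condition
        )


def simulate_motor_angle(spec: BeadSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Jump times and sampled motor angles of the dwell process.

    Returns ``(jump_times, motor_angle)`` where ``motor_angle`` is the
    piecewise-constant angle at the uniform sample times: the motor starts
    at angle 0 and advances by 2*pi/N at each jump, dwell durations drawn
    i.i.d. exponential with mean ``mean_dwell_time / deenergization_factor``.
    """
    rng = np.random.default_rng(spec.seed)
    mean_dwell = spec.mean_dwell_time / spec.deenergization_factor
    n_expected = int(spec.duration / mean_dwell * 1.5) + 64
    dwells = rng.exponential(mean_dwell, size=n_expected)
    jump_times = np.cumsum(dwells)
    while jump_times[-1] < spec.duration:
        extra = rng.exponential(mean_dwell, size=n_expected)
        jump_times = np.concatenate([jump_times, jump_times[-1] + np.cumsum(extra)])
    jump_times = jump_times[jump_times <= spec.duration]
    n_samples = int(np.floor(spec.duration * spec.sample_rate))
    t = np.arange(n_samples) / spec.sample_rate
    steps_taken = np.searchsorted(jump_times, t, side="right")
    motor_angle = steps_taken * (2.0 * np.pi / spec.n_dwells)
    return jump_times, motor_angle


def simulate_bead(spec: BeadSimSpec, condition: str = "") -> BeadTrajectory:
    """Simulate a bead x,y trace; pure function of the spec (incl. seed).

    Observed angle = motor angle + per-sample linkage noise; the bead sits
    at the parametric-angle point of the spec's ellipse plus isotropic
    localization noise.  Warns when the recording is too short to resolve
    the dwell structure (< 10 samples per dwell position).
    """
    n_samples = int(np.floor(spec.duration * spec.sample_rate))
    if n_samples < 10 * spec.n_dwells:
        warnings.warn(
            f"only {n_samples} samples for {spec.n_dwells} dwell positions; "
            "dwell recovery is underpowered",
            stacklevel=2,
        )
    _, motor_angle = simulate_motor_angle(spec)
    # independent noise stream so the jump process is unchanged by noise settings
    rng = np.random.default_rng((spec.seed, 1))
    phi = motor_angle
    if spec.linkage_sd > 0:
        phi = phi + rng.normal(0.0, spec.linkage_sd, size=n_samples)
    e = spec.ellipse
    co, so = np.cos(e.orientation), np.sin(e.orientation)
    ux = e.semi_major * np.cos(phi)
    uy = e.semi_minor * np.sin(phi)
    x = e.center[0] + co * ux - so * uy
    y = e.center[1] + so * ux + co * uy
    if spec.localization_sd > 0:
        x = x + rng.normal(0.0, spec.localization_sd, size=n_samples)
        y = y + rng.normal(0.0, spec.localization_sd, size=n_samples)
    t = np.arange(n_samples) / spec.sample_rate
    return BeadTrajectory(t, x, y, condition=condition)
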