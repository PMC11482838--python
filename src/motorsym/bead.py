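"""Dwell-position analysis of tethered-bead rotation traces.

Pipeline: fit the projected orbit ellipse, invert it to recover the motor
angle, build an occupancy-weighted circular (von Mises) kernel density
over angle, take the weighted power spectrum at integer harmonics, and
call the dwell count as the dominant harmonic.  Phase stability across
conditions (e.g. CCCP titrations) is judged by circular cross-correlation
of the dwell densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .beadsim import BeadTrajectory

#: harmonic search window for dwell counting; brackets the 26-fold
#: bushing periodicity with margin and excludes slow-drift harmonics
STEP_M_MIN = 10
STEP_M_MAX = 50


@dataclass
class EllipseFit:
    """Geometric parameters of the fitted orbit ellipse."""

    center: np.ndarray
    semi_major: float
    semi_minor: float
    orientation: float
    residual_rms: float


def fit_ellipse(t: BeadTrajectory) -> EllipseFit:
    """Direct algebraic least-squares ellipse fit (ellipse-constrained).

    Numerically stable variant of the Fitzgibbon direct fit: the conic
    coefficients minimize the algebraic residual subject to the ellipse
    constraint 4ac - b^2 = 1, which cannot return a hyperbola or parabola.
    Degenerate (collinear) inputs are rejected.
    """
    x = np.asarray(t.x, dtype=float)
    y = np.asarray(t.y, dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 points to fit an ellipse")
    mx, my = x.mean(), y.mean()
    sx = x - mx
    sy = y - my
    scale = np.sqrt(np.mean(sx**2 + sy**2))
    if scale == 0:
        raise ValueError("degenerate input: all points coincide")
    sx /= scale
    sy /= scale
    d1 = np.column_stack([sx**2, sx * sy, sy**2])
    d2 = np.column_stack([sx, sy, np.ones_like(sx)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t_mat = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate (collinear) input for ellipse fit") from exc
    m = s1 + s2 @ t_mat
    # premultiply by inv(C1) for constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m_red = np.vstack([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m_red)
    ev = np.real(eigvec)
    cond = 4.0 * ev[0] * ev[2] - ev[1] ** 2
    valid = np.where((np.abs(np.imag(eigval)) < 1e-8) & (cond > 0))[0]
    if len(valid) == 0:
        raise ValueError("degenerate (collinear) input: no ellipse solution")
    a1 = np.real(eigvec[:, valid[0]])
    conic = np.concatenate([a1, t_mat @ a1])  # A, B, C, D, E, F in scaled frame
    geom = _conic_to_geometry(conic)
    if geom is None:
        raise ValueError("conic fit did not yield a real ellipse")
    cx, cy, a, b, phi = geom
    center = np.array([cx * scale + mx, cy * scale + my])
    a *= scale
    b *= scale
    # residual: rms deviation of the normalized radius from 1, in length units
    co, so = np.cos(phi), np.sin(phi)
    ux = co * (x - center[0]) + so * (y - center[1])
    uy = -so * (x - center[0]) + co * (y - center[1])
    rho = np.sqrt((ux / a) ** 2 + (uy / b) ** 2)
    residual = float(np.sqrt(np.mean((rho - 1.0) ** 2)) * np.sqrt(a * b))
    return EllipseFit(center, float(a), float(b), float(phi % np.pi), residual)


def _conic_to_geometry(c: np.ndarray):
    a_, b_, c_, d_, e_, f_ = c
    m = np.array([[a_, b_ / 2.0], [b_ / 2.0, c_]])
    det = np.linalg.det(m)
    if det <= 0:
        return None
    centre = np.linalg.solve(2.0 * m, [-d_, -e_])
    f0 = (
        a_ * centre[0] ** 2
        + b_ * centre[0] * centre[1]
        + c_ * centre[1] ** 2
        + d_ * centre[0]
        + e_ * centre[1]
        + f_
    )
    eigval, eigvec = np.linalg.eigh(m)
    with np.errstate(invalid="ignore"):
        axes = np.sqrt(-f0 / eigval)
    if not np.all(np.isfinite(axes)):
        return None
    # smaller eigenvalue -> larger axis (major)
    order = np.argsort(axes)[::-1]
    major, minor = axes[order]
    vec = eigvec[:, order[0]]
    phi = float(np.arctan2(vec[1], vec[0]))
    return centre[0], centre[1], float(major), float(minor), phi


@dataclass
class AngularTrace:
    """Unwrapped rotation angle vs time for one bead."""

    time: np.ndarray
    angle: np.ndarray
    condition: str = ""

    @property
    def revolutions(self) -> float:
        """Signed net revolutions over the trace."""
        return float((self.angle[-1] - self.angle[0]) / (2.0 * np.pi))

    def wrapped(self) -> np.ndarray:
        return np.mod(self.angle, 2.0 * np.pi)

    def dt(self) -> np.ndarray:
        """Per-sample occupancy time (last step repeated)."""
        d = np.diff(self.time)
        return np.append(d, d[-1] if len(d) else 1.0)


def to_angle(
    t: BeadTrajectory, ellipse: EllipseFit | None, correct: bool = True
) -> AngularTrace:
    """Recover the unwrapped motor angle from bead positions.

    With ``correct=True`` the points are mapped to the unit circle by
    inverting the fitted centre, orientation and axis scaling before the
    angle is taken (removing the 2-per-revolution speed artefact of an
    elliptical projection); ``correct=False`` only re-centres.
    """
    if ellipse is None:
        ellipse = fit_ellipse(t)
    dx = t.x - ellipse.center[0]
    dy = t.y - ellipse.center[1]
    at_centre = (dx == 0) & (dy == 0)
    if at_centre.any():
        warnings.warn(
            f"{int(at_centre.sum())} sample(s) at the exact orbit centre; "
            "their angle is undefined",
            stacklevel=2,
        )
    co, so = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    ux = co * dx + so * dy
    uy = -so * dx + co * dy
    if correct:
        ux = ux / ellipse.semi_major
        uy = uy / ellipse.semi_minor
    raw = np.arctan2(uy, ux)
    return AngularTrace(np.asarray(t.time, float), np.unwrap(raw), t.condition)


@dataclass
class DwellDensity:
    """Circular probability density of dwell angle on a uniform grid."""

    theta: np.ndarray
    density: np.ndarray
    kappa: float

    @property
    def grid_step(self) -> float:
        return float(self.theta[1] - self.theta[0])


def kappa_for_harmonic(m_max: int = STEP_M_MAX) -> float:
    """Von Mises concentration whose kernel FWHM is half a 2*pi/m_max dwell
    spacing, i.e. sharp enough to resolve up to m_max dwell positions."""
    half_width = 0.5 * (2.0 * np.pi / m_max) / 2.0
    return float(np.log(2.0) / (1.0 - np.cos(half_width)))


def circular_kde(
    trace: AngularTrace, kappa: float | None = None, n_grid: int = 2048
) -> DwellDensity:
    """Occupancy-weighted von Mises kernel density over wrapped angle.

    Each sample is weighted by its time step, so slow (de-energized)
    segments dominate, and the result integrates to 1 over [0, 2*pi).
    """
    if kappa is None:
        kappa = kappa_for_harmonic()
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    theta = 2.0 * np.pi * np.arange(n_grid) / n_grid
    step = 2.0 * np.pi / n_grid
    w = trace.dt()
    # half-bin shift assigns each sample to its *nearest* grid angle
    shifted = np.mod(trace.wrapped() + step / 2.0, 2.0 * np.pi)
    hist, _ = np.histogram(shifted, bins=n_grid, range=(0.0, 2.0 * np.pi), weights=w)
    hist = hist / w.sum()
    # von Mises kernel via i0e to stay finite at large concentration
    centred = np.angle(np.exp(1j * theta))  # theta wrapped to (-pi, pi]
    kernel = np.exp(kappa * (np.cos(centred) - 1.0)) / (
        2.0 * np.pi * special.i0e(kappa)
    )
    density = np.fft.ifft(np.fft.fft(hist) * np.fft.fft(kernel)).real
    density = np.clip(density, 0.0, None)
    density /= density.sum() * step
    return DwellDensity(theta, density, float(kappa))


def density_harmonics(d: DwellDensity, m_max: int = 64) -> np.ndarray:
    """|Fourier coefficient|^2 of a dwell density at harmonics 1..m_max."""
    step = d.grid_step
    coeff = np.fft.fft(d.density) * step
    power = np.abs(coeff[1 : m_max + 1]) ** 2
    return power


@dataclass
class StepSpectrum:
    """Power vs integer harmonic of the angular occupancy density.

    Combined over traces with weights proportional to revolution count;
    ``weights`` records the per-trace weights used (they sum to 1).
    """

    m: np.ndarray
    power: np.ndarray
    weights: np.ndarray


def step_spectrum(traces: list[AngularTrace], m_max: int = 64) -> StepSpectrum:
    """Weighted power spectrum of angular position across traces.

    Per trace, power[m] is the squared magnitude of the occupancy-weighted
    circular moment ``sum_i w_i exp(-i m theta_i) / sum_i w_i`` — the
    Fourier coefficient of the empirical occupancy-weighted angular
    density (m = 0 excluded).  Traces are combined by a weighted mean with
    weight proportional to their number of revolutions; traces with fewer
    than 2 revolutions are excluded with a warning.
    """
    if not traces:
        raise ValueError("need at least one trace")
    kept, powers, revs = [], [], []
    for tr in traces:
        nrev = abs(tr.revolutions)
        if nrev < 2.0:
            warnings.warn(
                f"trace '{tr.condition}' has {nrev:.2f} revolutions (< 2); excluded",
                stacklevel=2,
            )
            continue
        w = tr.dt()
        theta = tr.wrapped()
        m = np.arange(1, m_max + 1)
        moments = np.exp(-1j * np.outer(m, theta)) @ w / w.sum()
        kept.append(tr)
        powers.append(np.abs(moments) ** 2)
        revs.append(nrev)
    if not kept:
        raise ValueError("no trace has >= 2 revolutions")
    weights = np.asarray(revs) / np.sum(revs)
    combined = np.einsum("t,tm->m", weights, np.asarray(powers))
    return StepSpectrum(np.arange(1, m_max + 1), combined, weights)


@dataclass
class StepCall:
    """Dwell-count call from a step spectrum."""

    n: int | None
    confidence: float
    alias_candidate: int | None = None

    @property
    def called(self) -> bool:
        return self.n is not None


def count_steps(
    s: StepSpectrum,
    m_min: int = STEP_M_MIN,
    m_max: int = STEP_M_MAX,
    confidence_threshold: float = 8.0,
) -> StepCall:
    """Call the dwell count as the dominant harmonic in [m_min, m_max].

    confidence = peak / median power over the window.  For featureless
    spectra the window maximum of near-exponentially distributed powers
    sits around ln(W)/ln(2) ~ 5x the median, hence the no-call threshold
    of 8.  Harmonic-alias guard: when the called n is even and the
    sub-harmonic n/2 carries more power, n/2 is reported as a candidate in
    the diagnostics.
    """
    sel = (s.m >= m_min) & (s.m <= m_max)
    if not sel.any():
        raise ValueError(f"window [{m_min}, {m_max}] outside spectrum")
    window_m = s.m[sel]
    window_p = s.power[sel]
    if not np.any(window_p > 0):
        return StepCall(None, 0.0)
    i = int(np.argmax(window_p))
    med = float(np.median(window_p))
    confidence = float(window_p[i] / med) if med > 0 else np.inf
    if confidence < confidence_threshold:
        return StepCall(None, confidence)
    n = int(window_m[i])
    alias = None
    if n % 2 == 0:
        half = n // 2
        p_half = s.power[s.m == half]
        if len(p_half) and p_half[0] > window_p[i]:
            alias = half
    return StepCall(n, confidence, alias)


@dataclass
class PhaseInvarianceResult:
    """Pairwise dwell-phase comparison across conditions."""

    max_lag: float
    lags: list[float]
    n_dwells: int
    passes: bool


def phase_invariance(
    densities: list[DwellDensity], n_dwells: int
) -> PhaseInvarianceResult:
    """Maximum pairwise circular cross-correlation lag between densities.

    For every pair, the lag maximizing the circular cross-correlation is
    found (parabola-refined to sub-grid precision) and reduced modulo the
    dwell spacing 2*pi/n_dwells into (-pi/N, pi/N] — an N-fold periodic
    density correlates equally at every multiple of the spacing, and only
    the misalignment of the dwell *lattice* is at issue.  The pattern is
    judged phase-invariant when every reduced |lag| stays below half the
    dwell spacing, pi/n_dwells (boundary cases within half a grid step of
    the limit count as failing).
    """
    if len(densities) < 2:
        raise ValueError("need at least two densities")
    n_grid = len(densities[0].theta)
    for d in densities[1:]:
        if len(d.theta) != n_grid or d.grid_step != densities[0].grid_step:
            raise ValueError("densities must share one angular grid")
    step = densities[0].grid_step
    lags = []
    for i in range(len(densities)):
        for j in range(i + 1, len(densities)):
            f1 = np.fft.fft(densities[i].density)
            f2 = np.fft.fft(densities[j].density)
            corr = np.fft.ifft(f1 * np.conj(f2)).real
            k = int(np.argmax(corr))
            cm, c0, cp = corr[(k - 1) % n_grid], corr[k], corr[(k + 1) % n_grid]
            denom = cm - 2.0 * c0 + cp
            shift = 0.0 if denom == 0 else float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))
            lag = (k + shift) * step
            spacing = 2.0 * np.pi / n_dwells
            lag = lag - spacing * np.round(lag / spacing)  # reduce mod spacing
            lags.append(float(lag))
    max_lag = float(np.max(np.abs(lags)))
    limit = np.pi / n_dwells - step / 2.0
    return PhaseInvarianceResult(max_lag, lags, n_dwells, passes=max_lag < limit)


def count_steps_from_trajectory(
    t: BeadTrajectory,
    m_min: int = STEP_M_MIN,
    m_max: int = STEP_M_MAX,
    correct_ellipse: bool = True,
) -> tuple[StepCall, StepSpectrum, AngularTrace]:
    """Full single-trace pipeline: ellipse fit -> angle -> spectrum -> call."""
    ellipse = fit_ellipse(t)
    trace = to_angle(t, ellipse, correct=correct_ellipse)
    spectrum = step_spectrum([trace], m_max=max(m_max + 14, 64))
    return count_steps(spectrum, m_min=m_min, m_max=m_max), spectrum, trace
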