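"""Synthetic B-mode speckle phantom with analytic ground truth.

Emulates the bench acquisitions: a speckle-filled tongue slab imaged from
below (transducer at the image bottom), a bright dorsal-surface interface,
faint gel echoes above it, an imposed compression/shear displacement field
with kinematic stick-slip at the surface, and synchronized synthetic force
traces.  All displacement closed forms are exposed so downstream estimators
(contour tracking, PIV, friction-phase detection) can be validated against
exact ground truth.

Material coordinates: ``x`` is the lateral position in mm (0 at the array
center), ``h`` the height in mm above the tongue base (the transducer face).
Pixel rows increase downward; the base sits on the bottom row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import hilbert

from .protocol import (
    HORIZONTAL,
    SHEAR,
    ForceTrace,
    MotionProtocol,
    MotionSchedule,
    build_schedule,
)

__all__ = [
    "ScattererField",
    "DeformationModel",
    "ImagingConfig",
    "PhantomGeometry",
    "FrameStack",
    "GroundTruth",
    "generate_scatterers",
    "displacement_at",
    "render_frame",
    "render_sequence",
    "surface_velocity_trace",
    "synthesize_forces",
    "shear_state",
    "stick_durations",
]

BULK = "tongue_bulk"
SURFACE = "surface_interface"
GEL = "gel"


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomGeometry:
    """Material extent of the phantom slab (mm)."""

    width: float = 36.0
    tongue_height: float = 20.0
    gel_thickness: float = 6.0
    surface_spacing: float = 0.12  # lateral spacing of interface scatterers
    surface_amplitude_factor: float = 4.0  # vs bulk mean amplitude
    surface_taper: float = 2.0  # mm; interface echo rolls off at the slab ends
    gel_amplitude_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.width <= 0 or self.tongue_height <= 0:
            raise PhantomError("degenerate geometry")


@dataclass(frozen=True)
class ScattererField:
    """Point scatterers in material coordinates."""

    x: np.ndarray  # mm, lateral
    h: np.ndarray  # mm, height above base
    amplitude: np.ndarray
    phase: np.ndarray  # carrier phase, used only in rf_mode rendering
    label: np.ndarray  # str codes: tongue_bulk | surface_interface | gel

    def __post_init__(self) -> None:
        for name in ("x", "h", "amplitude", "phase"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "label", np.asarray(self.label))
        if np.any(self.amplitude <= 0) and self.amplitude.size:
            raise PhantomError("scatterer amplitudes must be positive")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class DeformationModel:
    """Kinematic deformation of the tongue slab under the imposed motions.

    Vertical: a fraction ``compression_share`` of the vertical stage
    displacement is absorbed by the tongue, shaped laterally by a Gaussian
    contact profile of width ``contact_width`` and decaying linearly with
    depth (h/H profile, zero at the transducer-fixed base).

    Horizontal: the surface sticks to the palate until the elastic surface
    displacement reaches ``static_friction_threshold``; it then slips,
    relaxing exponentially toward ``slip_retention`` times the threshold.
    When a stroke stops, the stored displacement relaxes toward a residual.
    A mild ``stick_hardening`` velocity ramp during stick makes the surface
    velocity extremum occur exactly at the slip instant.
    """

    tongue_height: float = 20.0
    compression_share: float = 0.4
    contact_width: float = 6.0
    shear_gradient: float = 1.0
    static_friction_threshold: float = 2.0
    slip_retention: float = 0.6
    fracture_time: float | None = None
    stick_hardening: float = 0.2  # 1/s, relative velocity ramp during stick
    slip_tau: float = 0.5  # s, relaxation during slip
    stop_tau: float = 0.6  # s, relaxation after a stroke stops
    residual_fraction: float = 0.3  # of stored displacement kept at rest

    def __post_init__(self) -> None:
        if not 0.0 <= self.compression_share <= 1.0:
            raise PhantomError("compression_share must be within [0, 1]")
        if not 0.0 <= self.slip_retention <= 1.0:
            raise PhantomError("slip_retention must be within [0, 1]")
        if self.tongue_height <= 0:
            raise PhantomError("tongue_height must be positive")


@dataclass(frozen=True)
class ImagingConfig:
    """Rendering parameters of the synthetic scanner."""

    pixels_per_mm: float = 18.3
    frame_size: tuple[int, int] = (512, 768)  # (depth px, width px)
    psf_sigma_axial: float = 1.2
    psf_sigma_lateral: float = 2.0
    rf_mode: bool = False
    noise_floor: float = 4.0
    noise_sigma: float = 2.0
    log_compression_gain: float = 40.0
    log_ref: float = 0.7  # envelope amplitude mapped to full white
    centre_frequency_mhz: float = 6.0
    sound_speed: float = 1540.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels_per_mm <= 0:
            raise PhantomError("pixels_per_mm must be positive")
        depth, width = self.frame_size
        if depth < 128 or width < 370:
            raise PhantomError("frame must accommodate at least a 370x105 px ROI")


@dataclass(frozen=True)
class FrameStack:
    """Ordered 8-bit frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, depth, width) uint8
    frame_rate: float
    pixels_per_mm: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n, depth, width) array")
        if frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate


# ---------------------------------------------------------------------------
# stick-slip surface state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Piece:
    t0: float
    t1: float
    kind: str  # stick | slip | relax
    # stick: s(t) = s0 + v*(dt + hard*dt^2/2)
    # slip/relax: s(t) = s_inf + (s0 - s_inf)*exp(-dt/tau)
    s0: float
    v: float = 0.0
    hard: float = 0.0
    s_inf: float = 0.0
    tau: float = 1.0

    def eval(self, t: np.ndarray) -> np.ndarray:
        dt = t - self.t0
        if self.kind == "stick":
            return self.s0 + self.v * (dt + self.hard * dt**2 / 2.0)
        return self.s_inf + (self.s0 - self.s_inf) * np.exp(-dt / self.tau)

    def end_value(self) -> float:
        return float(self.eval(np.asarray(self.t1)))


def _stick_time_to_slip(s0: float, v: float, hard: float, threshold: float) -> float | None:
    """Time for |s| to grow from s0 to the signed threshold, or None."""
    sg = math.copysign(1.0, v)
    target = sg * threshold - s0
    if sg * target <= 0:  # already at/beyond threshold in this direction
        return 0.0
    w = abs(v)
    mag = abs(target)
    if hard <= 0:
        return mag / w
    # w*(dt + hard*dt^2/2) = mag
    disc = w * w + 2.0 * w * hard * mag
    return (-w + math.sqrt(disc)) / (w * hard)


def shear_state(model: DeformationModel, schedule: MotionSchedule) -> list[_Piece]:
    """Piecewise closed form of the elastic surface shear displacement (mm)."""
    pieces: list[_Piece] = []
    s = 0.0
    theta = model.static_friction_threshold
    for seg in schedule.segments:
        if seg.phase == SHEAR and seg.axis == HORIZONTAL and seg.velocity != 0.0:
            sg = math.copysign(1.0, seg.velocity)
            dt_slip = _stick_time_to_slip(s, seg.velocity, model.stick_hardening, theta)
            if dt_slip is None or dt_slip >= seg.duration:
                pieces.append(_Piece(seg.t_start, seg.t_end, "stick", s, seg.velocity, model.stick_hardening))
                s = pieces[-1].end_value()
            else:
                t_slip = seg.t_start + dt_slip
                if dt_slip > 0:
                    pieces.append(_Piece(seg.t_start, t_slip, "stick", s, seg.velocity, model.stick_hardening))
                s_at_slip = sg * theta if dt_slip > 0 else s
                hold = sg * model.slip_retention * theta
                pieces.append(_Piece(t_slip, seg.t_end, "slip", s_at_slip, s_inf=hold, tau=model.slip_tau))
                s = pieces[-1].end_value()
        else:
            residual = model.residual_fraction * s
            pieces.append(_Piece(seg.t_start, seg.t_end, "relax", s, s_inf=residual, tau=model.stop_tau))
            s = pieces[-1].end_value()
    return pieces


def stick_durations(model: DeformationModel, schedule: MotionSchedule) -> list[float | None]:
    """Per-stroke stick (static-friction) phase duration in s; None = no slip."""
    pieces = shear_state(model, schedule)
    out: list[float | None] = []
    for stroke in schedule.strokes():
        stick = [p for p in pieces if p.kind == "stick" and abs(p.t0 - stroke.t_start) < 1e-9]
        slips = [p for p in pieces if p.kind == "slip" and stroke.t_start - 1e-9 <= p.t0 < stroke.t_end]
        if not slips:
            out.append(None)
        elif stick:
            out.append(stick[0].t1 - stick[0].t0)
        else:
            out.append(0.0)
    return out


def _eval_shear(pieces: Sequence[_Piece], t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    s = np.zeros_like(t)
    if not pieces:
        return s
    for i, p in enumerate(pieces):
        if i == len(pieces) - 1:
            mask = (t >= p.t0 - 1e-12) & (t <= p.t1 + 1e-12)
        else:
            mask = (t >= p.t0 - 1e-12) & (t < p.t1)
        if np.any(mask):
            s[mask] = p.eval(t[mask])
    return s


# ---------------------------------------------------------------------------
# displacement field
# ---------------------------------------------------------------------------

def displacement_at(
    model: DeformationModel,
    schedule: MotionSchedule,
    x,
    h,
    t: float,
    _pieces: Sequence[_Piece] | None = None,
):
    """Material displacement (u_x, u_y) in mm at lateral position(s) ``x`` and
    height(s) ``h`` above the base, at time ``t``.

    ``u_y`` is signed along the height axis: negative means the point moves
    down toward the transducer (compression).  Points above the tongue
    surface (h > H) move with the surface.
    """
    if t < -1e-12 or t > schedule.total_duration + 1e-9:
        raise PhantomError(f"t={t} outside schedule")
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    H = model.tongue_height
    frac = np.clip(h, 0.0, H) / H

    sv = schedule.position_at(t, "vertical")
    g = np.exp(-(x**2) / (2.0 * model.contact_width**2))
    u_y = -model.compression_share * sv * frac * g

    pieces = shear_state(model, schedule) if _pieces is None else _pieces
    s = float(_eval_shear(pieces, np.asarray([t]))[0])
    u_x = model.shear_gradient * s * frac
    return np.broadcast_to(u_x, np.broadcast_shapes(x.shape, h.shape)).copy(), u_y


# ---------------------------------------------------------------------------
# scatterer generation & rendering
# ---------------------------------------------------------------------------

def generate_scatterers(
    geometry: PhantomGeometry,
    density: float,
    seed: int = 0,
) -> ScattererField:
    """Draw bulk, interface, and gel scatterers.

    Bulk count is Poisson(density x area) with uniform positions; interface
    scatterers sit densely along the dorsal surface with amplitudes well
    above the bulk mean; gel echoes above the surface are weak.
    """
    if density < 0:
        raise PhantomError("density must be non-negative")
    rng = np.random.default_rng(seed)
    half_w = geometry.width / 2.0
    H = geometry.tongue_height

    n_bulk = rng.poisson(density * geometry.width * H) if density > 0 else 0
    xb = rng.uniform(-half_w, half_w, n_bulk)
    hb = rng.uniform(0.0, H, n_bulk)
    # Rayleigh amplitudes: positive, unit-ish mean, realistic spread
    ab = rng.rayleigh(scale=0.8, size=n_bulk)
    ab = np.clip(ab, 0.05, None)

    if density > 0:
        n_surf = max(int(geometry.width / geometry.surface_spacing), 2)
        xs = np.linspace(-half_w, half_w, n_surf) + rng.normal(0.0, 0.02 * geometry.surface_spacing, n_surf)
        hs = np.full(n_surf, H) + rng.normal(0.0, 0.02, n_surf)
        amps = geometry.surface_amplitude_factor * (1.0 + 0.1 * rng.standard_normal(n_surf))
        if geometry.surface_taper > 0:
            # echo rolloff toward the slab ends keeps the detected band away
            # from the lateral image borders (mirrors array-edge sensitivity)
            taper = np.clip((half_w - np.abs(xs)) / geometry.surface_taper, 0.0, 1.0)
            amps = amps * taper
        amps = np.clip(amps, 0.02, None)

        n_gel = rng.poisson(0.5 * density * geometry.width * geometry.gel_thickness)
        xg = rng.uniform(-half_w, half_w, n_gel)
        hg = rng.uniform(H, H + geometry.gel_thickness, n_gel)
        ag = np.clip(geometry.gel_amplitude_factor * rng.rayleigh(scale=0.8, size=n_gel), 0.01, None)
    else:
        xs = hs = amps = xg = hg = ag = np.empty(0)

    x = np.concatenate([xb, xs, xg])
    h = np.concatenate([hb, hs, hg])
    amp = np.concatenate([ab, amps, ag])
    label = np.concatenate([
        np.full(len(xb), BULK),
        np.full(len(xs), SURFACE),
        np.full(len(xg), GEL),
    ])
    phase = rng.uniform(0.0, 2.0 * np.pi, x.size)
    return ScattererField(x, h, amp, phase, label)


def _material_to_pixels(config: ImagingConfig, x: np.ndarray, h: np.ndarray):
    depth, width = config.frame_size
    cols = x * config.pixels_per_mm + (width - 1) / 2.0
    rows = (depth - 1) - h * config.pixels_per_mm
    return rows, cols


def _deposit(rows, cols, weights, shape) -> np.ndarray:
    """Bilinear scatter-add of point amplitudes onto the pixel grid."""
    img = np.zeros(shape)
    inside = (rows > -1) & (rows < shape[0]) & (cols > -1) & (cols < shape[1])
    r, c, w = rows[inside], cols[inside], weights[inside]
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        np.add.at(img, (rr[ok], cc[ok]), (w * wt)[ok])
    return img


def _noise_pattern(config: ImagingConfig) -> np.ndarray:
    # Fixed pattern: content-independent, identical across frames so that a
    # static scene renders bitwise-identical frames.
    rng = np.random.default_rng((config.seed, 0xB0DE))
    return rng.standard_normal(config.frame_size)


def render_frame(
    scatterers: ScattererField,
    config: ImagingConfig,
    displacement: tuple[np.ndarray, np.ndarray] | None = None,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Render one 8-bit frame from (displaced) scatterers.

    Envelope mode sums Gaussian point-spread contributions; rf_mode instead
    sums a 6 MHz two-way carrier per scatterer and takes the magnitude of
    the depth-axis analytic signal.  The envelope is log-compressed against
    a fixed reference and quantized, then a fixed noise pattern around the
    noise floor is added.
    """
    ux, uy = displacement if displacement is not None else (0.0, 0.0)
    rows, cols = _material_to_pixels(config, scatterers.x + ux, scatterers.h + uy)

    if config.rf_mode:
        # two-way carrier: spatial period = c / (2 f0), expressed in px
        wavelength_px = (config.sound_speed / (2.0 * config.centre_frequency_mhz * 1e6)) * 1e3 * config.pixels_per_mm
        carrier = np.cos(2.0 * np.pi * rows / wavelength_px + scatterers.phase)
        rf = _deposit(rows, cols, scatterers.amplitude * carrier, config.frame_size)
        rf = gaussian_filter(rf, (config.psf_sigma_axial, config.psf_sigma_lateral), mode="constant")
        envelope = np.abs(hilbert(rf, axis=0))
    else:
        envelope = _deposit(rows, cols, scatterers.amplitude, config.frame_size)
        envelope = gaussian_filter(envelope, (config.psf_sigma_axial, config.psf_sigma_lateral), mode="constant")

    g = config.log_compression_gain
    img = 255.0 * np.log1p(g * envelope) / np.log1p(g * config.log_ref)
    if noise is None:
        noise = _noise_pattern(config)
    img = img + config.noise_floor + config.noise_sigma * noise
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# ground truth & sequence rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Analytic oracle for the rendered sequence.

    ``surface_depth[k, j]`` is the sub-pixel row of the dorsal surface at
    frame k and lateral station j (stations uniform over the frame width).
    Velocity queries differentiate the displacement closed forms.
    """

    times: np.ndarray
    station_cols: np.ndarray
    surface_depth: np.ndarray  # (n_frames, n_stations) rows in px
    model: DeformationModel
    schedule: MotionSchedule
    config: ImagingConfig

    def _pieces(self):
        if not hasattr(self, "_pieces_cache"):
            object.__setattr__(self, "_pieces_cache", shear_state(self.model, self.schedule))
        return self._pieces_cache

    def surface_shear_mm(self, t) -> np.ndarray:
        """Elastic surface shear displacement s(t) in mm."""
        return self.model.shear_gradient * _eval_shear(self._pieces(), np.asarray(t, dtype=float))

    def surface_velocity_px_per_frame(self, pair_times: np.ndarray) -> np.ndarray:
        """Horizontal surface velocity over frame pairs starting at ``pair_times``."""
        dt = 1.0 / (self.times[1] - self.times[0]) if self.times.size > 1 else 1.0
        period = self.times[1] - self.times[0]
        s0 = self.surface_shear_mm(pair_times)
        s1 = self.surface_shear_mm(pair_times + period)
        return (s1 - s0) * self.config.pixels_per_mm

    def displacement_px(self, x_px, depth_px, t: float):
        """(u, v) pixel displacement of material points currently near the
        queried pixel coordinates, between frames at t and t + 1/frame_rate."""
        period = self.times[1] - self.times[0]
        depth_img, width = self.config.frame_size
        x_mm = (np.asarray(x_px, dtype=float) - (width - 1) / 2.0) / self.config.pixels_per_mm
        h_mm = ((depth_img - 1) - np.asarray(depth_px, dtype=float)) / self.config.pixels_per_mm
        ux0, uy0 = displacement_at(self.model, self.schedule, x_mm, h_mm, t, _pieces=self._pieces())
        ux1, uy1 = displacement_at(self.model, self.schedule, x_mm, h_mm, t + period, _pieces=self._pieces())
        u = (ux1 - ux0) * self.config.pixels_per_mm
        v = -(uy1 - uy0) * self.config.pixels_per_mm  # rows grow downward
        return u, v


def render_sequence(
    protocol: MotionProtocol,
    model: DeformationModel,
    config: ImagingConfig,
    geometry: PhantomGeometry | None = None,
    density: float = 6.0,
    n_stations: int = 100,
    gel_modulus_kpa: float = 18.35,
    tongue_modulus_kpa: float = 25.57,
) -> tuple[FrameStack, GroundTruth, ForceTrace]:
    """Render the full imposed-motion sequence with ground truth and forces."""
    geometry = geometry or PhantomGeometry(tongue_height=model.tongue_height)
    schedule = build_schedule(protocol)
    pieces = shear_state(model, schedule)
    scatterers = generate_scatterers(geometry, density, seed=config.seed)
    noise = _noise_pattern(config)

    n_frames = int(np.floor(schedule.total_duration * protocol.frame_rate + 1e-9)) + 1
    times = np.arange(n_frames) / protocol.frame_rate

    depth_px, width_px = config.frame_size
    station_cols = np.linspace(0, width_px - 1, n_stations)
    x_station_mm = (station_cols - (width_px - 1) / 2.0) / config.pixels_per_mm

    frames = np.empty((n_frames, depth_px, width_px), dtype=np.uint8)
    surface = np.empty((n_frames, n_stations))
    H = model.tongue_height
    for k, t in enumerate(times):
        ux, uy = displacement_at(model, schedule, scatterers.x, scatterers.h, t, _pieces=pieces)
        frames[k] = render_frame(scatterers, config, (ux, uy), noise=noise)
        # the surface profile is advected laterally by the (uniform) surface
        # shear; evaluate the descent at the material abscissa that lands on
        # each station
        s_surf = model.shear_gradient * float(_eval_shear(pieces, np.asarray([t]))[0])
        xi = x_station_mm - s_surf
        _, uy_s = displacement_at(model, schedule, xi, np.full(n_stations, H), t, _pieces=pieces)
        surface[k] = (depth_px - 1) - (H + uy_s) * config.pixels_per_mm

    if surface.min() < 2 or surface.max() > depth_px - 3:
        raise PhantomError(
            f"deformed surface leaves the frame (rows {surface.min():.1f}..{surface.max():.1f} "
            f"of {depth_px}); shrink the deformation or enlarge the frame"
        )

    stack = FrameStack(frames, protocol.frame_rate, config.pixels_per_mm)
    truth = GroundTruth(times, station_cols, surface, model, schedule, config)
    forces = synthesize_forces(protocol, model, gel_modulus_kpa, tongue_modulus_kpa, seed=config.seed)
    return stack, truth, forces


def surface_velocity_trace(
    model: DeformationModel,
    schedule: MotionSchedule,
    frame_rate: float = 60.0,
    pixels_per_mm: float = 18.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic surface horizontal velocity sampled like a PIV frame-pair
    series: (pair start times, u in px/frame)."""
    pieces = shear_state(model, schedule)
    n = int(np.floor(schedule.total_duration * frame_rate + 1e-9))
    edges = np.arange(n + 1) / frame_rate
    s = model.shear_gradient * _eval_shear(pieces, edges)
    return edges[:-1], np.diff(s) * pixels_per_mm


def synthesize_forces(
    protocol: MotionProtocol,
    model: DeformationModel,
    gel_stiffness_kpa: float,
    tongue_stiffness_kpa: float,
    seed: int = 0,
    force_scale: float = 0.05,  # N per (kPa * mm), contact-area lumped constant
    mu_static: float = 0.8,
    mu_dynamic: float = 0.4,
    fracture_tau: float = 0.3,
    noise_sigma: float = 0.5,  # 1% of the +/-50 N sensor range
) -> ForceTrace:
    """Normal/tangential force traces from a springs-in-series contact model.

    Normal force is the equivalent series stiffness times the imposed
    vertical displacement; an optional fracture event decays the signal
    exponentially.  Tangential force is friction (static during stick,
    dynamic during slip) times the normal force, signed by stroke direction.
    """
    if gel_stiffness_kpa <= 0 or tongue_stiffness_kpa <= 0:
        raise PhantomError("stiffnesses must be positive")
    schedule = build_schedule(protocol)
    n = int(np.floor(schedule.total_duration * protocol.force_rate + 1e-9)) + 1
    n = max(n, 1)
    t = np.arange(n) / protocol.force_rate

    k_eq = 1.0 / (1.0 / gel_stiffness_kpa + 1.0 / tongue_stiffness_kpa)
    sv = np.atleast_1d(schedule.position_at(t, "vertical")) if schedule.segments else np.zeros(n)
    normal = force_scale * k_eq * sv
    if model.fracture_time is not None:
        after = t >= model.fracture_time
        normal = np.where(after, normal * np.exp(-(t - model.fracture_time) / fracture_tau), normal)

    tangential = np.zeros(n)
    pieces = shear_state(model, schedule)
    for p in pieces:
        if p.kind not in ("stick", "slip"):
            continue
        mu = mu_static if p.kind == "stick" else mu_dynamic
        sgn = math.copysign(1.0, p.v) if p.kind == "stick" else math.copysign(1.0, p.s_inf or p.s0)
        mask = (t >= p.t0) & (t < p.t1)
        tangential[mask] = mu * sgn * normal[mask]

    rng = np.random.default_rng((seed, 0xF0CE))
    normal = normal + rng.normal(0.0, noise_sigma, n)
    tangential = tangential + rng.normal(0.0, noise_sigma, n)
    return ForceTrace(t, normal, tangential, protocol.force_rate)
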