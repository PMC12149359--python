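"""Dorsal-surface tracking with an open active contour, plus unit views.

The contour is a function graph: 100 nodes at fixed lateral stations whose
depths evolve to minimize a weighted sum of internal (smoothness, bending)
and external (edge attraction) energy.  Optimization is a greedy discrete
search (coarse-to-fine image smoothing, step-size offsets, then a 1 px
polish and a parabolic sub-pixel fit), which keeps the energy monotonically
non-increasing and is robust on speckle.

Depth tables convert between pixel rows, millimetres (183 px per 10 mm) and
two-way pulse-echo time-of-flight at 1540 m/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import FrameStack
from .preproc import BinaryBand, preprocess_frame

__all__ = [
    "Contour",
    "SnakeParams",
    "ContourTable",
    "initialize_contour",
    "snake_evolve",
    "track_sequence",
    "depth_px_to_mm",
    "depth_mm_to_px",
    "depth_mm_to_tof",
    "fluctuation_map",
    "deformation_width",
]

logger = logging.getLogger(__name__)

PX_PER_10MM = 183.0
SOUND_SPEED = 1540.0  # m/s
N_STATIONS = 100


class ContourError(ValueError):
    pass


@dataclass(frozen=True)
class Contour:
    """Open surface contour: depth (px, sub-pixel) at fixed lateral stations."""

    stations: np.ndarray  # column coordinates, strictly increasing
    depth: np.ndarray  # rows, same length

    def __post_init__(self) -> None:
        stations = np.asarray(self.stations, dtype=float)
        depth = np.asarray(self.depth, dtype=float)
        if stations.size != depth.size:
            raise ContourError("stations and depths must align")
        if np.any(np.diff(stations) <= 0):
            raise ContourError("stations must be strictly increasing")
        object.__setattr__(self, "stations", stations)
        object.__setattr__(self, "depth", depth)

    def __len__(self) -> int:
        return self.stations.size


@dataclass(frozen=True)
class SnakeParams:
    """Active-contour weights and search parameters (published defaults)."""

    sigma_coarse: float = 5.0
    sigma_fine: float = 2.0
    delta: int = 2
    band_penalty: float = 2.0
    alpha: float = 0.80
    lambda_: float = 0.95
    max_iterations: int = 200
    convergence_tol: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.lambda_ <= 1.0):
            raise ContourError("alpha and lambda must lie in [0, 1]")
        if self.delta < 1:
            raise ContourError("delta must be at least 1 px")


@dataclass(frozen=True)
class ContourTable:
    """Per-frame surface depths at the 100 stations, in three unit views.

    ``depth_px`` are image rows (increasing downward).  The time-of-flight
    view converts the height of the surface above the transducer face (the
    bottom image row) into two-way echo time.
    """

    depth_px: np.ndarray  # (n_frames, n_stations)
    station_cols: np.ndarray
    frame_rate: float
    frame_depth_px: int
    pixels_per_mm: float = PX_PER_10MM / 10.0
    sound_speed: float = SOUND_SPEED

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_px", np.asarray(self.depth_px, dtype=float))
        object.__setattr__(self, "station_cols", np.asarray(self.station_cols, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.depth_px.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def depth_mm(self) -> np.ndarray:
        return self.depth_px / self.pixels_per_mm

    @property
    def height_above_transducer_mm(self) -> np.ndarray:
        return ((self.frame_depth_px - 1) - self.depth_px) / self.pixels_per_mm

    @property
    def tof_us(self) -> np.ndarray:
        return depth_mm_to_tof(self.height_above_transducer_mm, self.sound_speed)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def depth_px_to_mm(d, px_per_10mm: float = PX_PER_10MM):
    """Pixels to millimetres via the scanner's 183 px / 10 mm indication."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ContourError("depth must be non-negative")
    out = d * 10.0 / px_per_10mm
    return out if out.ndim else float(out)


def depth_mm_to_px(d, px_per_10mm: float = PX_PER_10MM):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ContourError("depth must be non-negative")
    out = d * px_per_10mm / 10.0
    return out if out.ndim else float(out)


def depth_mm_to_tof(d, sound_speed: float = SOUND_SPEED):
    """Two-way pulse-echo time-of-flight in microseconds for depth in mm."""
    if sound_speed <= 0:
        raise ContourError("sound speed must be positive")
    d = np.asarray(d, dtype=float)
    out = 2.0 * d * 1e3 / sound_speed  # (mm -> m is 1e-3, s -> us is 1e6)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# initialization & evolution
# ---------------------------------------------------------------------------

def default_stations(frame_width: int, n_stations: int = N_STATIONS) -> np.ndarray:
    """Uniform stations across the full width, endpoints inclusive."""
    return np.linspace(0, frame_width - 1, n_stations)


def initialize_contour(band: BinaryBand, n_stations: int = N_STATIONS) -> Contour:
    """Seed the contour from per-column band centroids.

    Stations whose column is empty, or whose centroid is pulled far from
    the local median profile by a spurious off-surface component, are
    filled by linear interpolation between valid neighbours.
    """
    centroids = band.column_centroids()
    stations = default_stations(band.shape[1], n_stations)
    cols = np.rint(stations).astype(int)
    depth = centroids[cols]
    valid = np.isfinite(depth)
    if valid.sum() < 0.5 * n_stations:
        raise ContourError(
            f"band empty in {(~valid).sum()}/{n_stations} stations; cannot initialize"
        )
    # reject centroids far from the local (9-station) median profile
    from scipy.signal import medfilt

    filled = np.interp(stations, stations[valid], depth[valid])
    local_med = medfilt(filled, kernel_size=9)
    valid &= np.abs(depth - local_med) <= 5.0
    if valid.sum() < 0.5 * n_stations:
        raise ContourError("band too fragmented to initialize a contour")
    depth = np.interp(stations, stations[valid], depth[valid])
    return Contour(stations, depth)


def _external_map(image: np.ndarray, sigma: float) -> np.ndarray:
    """Smoothed, max-normalized attraction map in [0, 1]."""
    ext = gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect")
    peak = ext.max()
    return ext / peak if peak > 0 else ext


def _snake_energy(depth: np.ndarray, ext_at: np.ndarray, params: SnakeParams, dx: float) -> float:
    d1 = np.diff(depth) / dx  # slope
    d2 = np.diff(depth, 2) / dx**2  # curvature
    e_int = float(np.sum(d1**2) + params.band_penalty * np.sum(d2**2))
    e_ext = -float(np.sum(ext_at))
    return params.alpha * e_int + params.lambda_ * e_ext


def _node_energy(depth: list, i: int, di: float, ext_val: float, params: SnakeParams, dx: float) -> float:
    """Sum of all energy terms that involve node i, with its depth set to di."""
    n = len(depth)
    s = 0.0
    if i > 0:
        s += ((di - depth[i - 1]) / dx) ** 2
    if i < n - 1:
        s += ((depth[i + 1] - di) / dx) ** 2
    b = 0.0
    for j in (i - 2, i - 1, i):
        if 0 <= j <= n - 3:
            dj = di if j == i else depth[j]
            dj1 = di if j + 1 == i else depth[j + 1]
            dj2 = di if j + 2 == i else depth[j + 2]
            b += ((dj - 2.0 * dj1 + dj2) / dx**2) ** 2
    return params.alpha * (s + params.band_penalty * b) - params.lambda_ * ext_val


def _greedy_pass(depth, ext, cols, params, dx, step: int) -> np.ndarray:
    """Sequential per-node search over {-step, 0, +step}; energy never rises.

    Moves are accepted from O(1) local energy deltas; the global energy is
    re-checked once per sweep to assert monotone descent.
    """
    n_rows = ext.shape[0]
    d = [float(v) for v in depth]
    col_list = [int(c) for c in cols]
    energy = _snake_energy(
        np.asarray(d), ext[np.clip(np.rint(d).astype(int), 0, n_rows - 1), cols], params, dx
    )
    for _ in range(params.max_iterations):
        moved = 0
        for i in range(len(d)):
            cur = d[i]
            best_d = cur
            best_e = _node_energy(d, i, cur, ext[int(round(cur)), col_list[i]], params, dx)
            for off in (-step, step):
                cand = cur + off
                if cand < 0 or cand > n_rows - 1:
                    continue
                e = _node_energy(d, i, cand, ext[int(round(cand)), col_list[i]], params, dx)
                if e < best_e - 1e-12:
                    best_e, best_d = e, cand
            if best_d != cur:
                d[i] = best_d
                moved += 1
        new_depth = np.asarray(d)
        new_energy = _snake_energy(
            new_depth, ext[np.clip(np.rint(d).astype(int), 0, n_rows - 1), cols], params, dx
        )
        assert new_energy <= energy + 1e-9, "snake energy increased"
        energy = new_energy
        if moved == 0:
            break
    return np.asarray(d)


def snake_evolve(image: np.ndarray, contour: Contour, params: SnakeParams = SnakeParams()) -> Contour:
    """Evolve the contour on ``image`` (coarse-to-fine), with sub-pixel polish.

    The external energy attracts nodes to bright/strong rows of the image
    (typically the preprocessed surface band); the internal energy penalizes
    slope and bending of the depth profile.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ContourError("image contains non-finite values")
    cols = np.clip(np.rint(contour.stations).astype(int), 0, image.shape[1] - 1)
    dx = float(np.mean(np.diff(contour.stations)))
    depth = np.clip(np.rint(contour.depth).astype(float), 0, image.shape[0] - 1)

    ext_fine = None
    for sigma in (params.sigma_coarse, params.sigma_fine):
        ext = _external_map(image, sigma)
        depth = _greedy_pass(depth, ext, cols, params, dx, step=params.delta)
        if params.delta > 1:
            depth = _greedy_pass(depth, ext, cols, params, dx, step=1)
        ext_fine = ext

    # parabolic sub-pixel refinement on the fine attraction profile
    d_int = np.rint(depth).astype(int)
    up = np.clip(d_int - 1, 0, image.shape[0] - 1)
    down = np.clip(d_int + 1, 0, image.shape[0] - 1)
    e0 = ext_fine[d_int, cols]
    em = ext_fine[up, cols]
    ep = ext_fine[down, cols]
    denom = em - 2.0 * e0 + ep
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(denom < -1e-12, 0.5 * (em - ep) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    return Contour(contour.stations, depth + shift)


def track_sequence(
    stack: FrameStack,
    params: SnakeParams = SnakeParams(),
    n_stations: int = N_STATIONS,
    reinit_threshold: float = 0.15,
) -> ContourTable:
    """Track the surface across all frames of a stack.

    Frame 0 is initialized from the preprocessed band; each later frame
    starts from the previous solution and evolves on its own preprocessed
    band.  If the contour loses the band (weak mean attraction), tracking
    re-initializes from that frame's band and logs a warning.
    """
    if len(stack) == 0:
        raise ContourError("empty frame stack")
    depths = np.empty((len(stack), n_stations))
    stations = default_stations(stack.frame_shape[1], n_stations)
    cols = np.rint(stations).astype(int)

    contour = None
    for k in range(len(stack)):
        band = preprocess_frame(stack.frames[k])
        image = band.mask.astype(float) * 255.0
        if contour is None:
            contour = initialize_contour(band, n_stations)
        else:
            contour = Contour(stations, depths[k - 1])
        contour = snake_evolve(image, contour, params)

        ext = _external_map(image, params.sigma_fine)
        attraction = float(
            np.mean(ext[np.clip(np.rint(contour.depth).astype(int), 0, image.shape[0] - 1), cols])
        )
        if attraction < reinit_threshold:
            try:
                reinit = initialize_contour(band, n_stations)
            except ContourError:
                reinit = None
            if reinit is not None:
                logger.warning("tracking loss at frame %d; re-initializing from band", k)
                contour = snake_evolve(image, reinit, params)
        depths[k] = contour.depth

    return ContourTable(
        depth_px=depths,
        station_cols=stations,
        frame_rate=stack.frame_rate,
        frame_depth_px=stack.frame_shape[0],
        pixels_per_mm=stack.pixels_per_mm,
    )


# ---------------------------------------------------------------------------
# derived maps
# ---------------------------------------------------------------------------

def fluctuation_map(table: ContourTable) -> np.ndarray:
    """(stations x frames) deviation of ToF from the first-frame baseline."""
    if table.n_frames < 2:
        raise ContourError("need at least two frames")
    tof = table.tof_us
    return (tof - tof[0]).T


def deformation_width(fluct: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Per-frame count of stations where |deviation| exceeds fraction x max."""
    if not 0.0 < fraction < 1.0:
        raise ContourError("fraction must be in (0, 1)")
    fluct = np.asarray(fluct, dtype=float)
    if fluct.size == 0:
        raise ContourError("empty map")
    peak = np.abs(fluct).max()
    if peak == 0:
        return np.zeros(fluct.shape[1], dtype=int)
    return (np.abs(fluct) > fraction * peak).sum(axis=0)
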