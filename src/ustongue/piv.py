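"""Velocity fields in a surface-anchored ROI by multipass FFT correlation.

Two passes (64 px then 32 px interrogation windows, 50% overlap): the first
pass yields a predictor displacement field, the second correlates against a
bilinearly warped copy of the later frame (window deformation) and adds a
correction.  Vectors are validated by correlation peak ratio and a
normalized-median neighbourhood test, with invalid nodes infilled from
valid neighbours.  Velocities are in px/frame, matching the source data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import map_coordinates
from skimage.exposure import equalize_adapthist

from .contour import ContourTable
from .phantom import FrameStack

__all__ = [
    "RoiSpec",
    "RoiPlacement",
    "PivConfig",
    "VelocityGrid",
    "VelocityHistory",
    "SurfaceTrace",
    "clahe",
    "anchor_roi",
    "grid_shape",
    "correlate_pair",
    "subpixel_peak",
    "piv_pair",
    "piv_sequence",
    "surface_trace",
    "depth_profile_map",
]


class PivError(ValueError):
    pass


@dataclass(frozen=True)
class RoiSpec:
    """Size of the analysis ROI; placement is anchored per experiment."""

    width: int = 370
    height: int = 105


@dataclass(frozen=True)
class RoiPlacement:
    """Concrete ROI position in frame coordinates (fixed over time)."""

    row0: int
    col0: int
    height: int
    width: int

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.row0 : self.row0 + self.height, self.col0 : self.col0 + self.width]


@dataclass(frozen=True)
class PivConfig:
    pass_windows: tuple[int, ...] = (64, 32)
    overlap_fraction: float = 0.5
    peak_ratio_min: float = 1.3
    peak_exclusion_radius: int = 5  # speckle correlation length, px
    norm_median_max: float = 2.0
    clahe_tiles: int = 8
    clahe_clip: float = 0.01

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.pass_windows, self.pass_windows[1:])):
            raise PivError("pass windows must decrease")
        if not 0.0 <= self.overlap_fraction <= 0.75:
            raise PivError("overlap must lie in [0, 0.75]")


@dataclass(frozen=True)
class VelocityGrid:
    """One frame pair's displacement field on the final interrogation grid."""

    row_px: np.ndarray  # node centers, ROI coordinates
    col_px: np.ndarray
    u: np.ndarray  # horizontal, px/frame, (rows, cols)
    v: np.ndarray  # vertical (down positive), px/frame
    valid: np.ndarray  # bool, False where the vector was infilled

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass(frozen=True)
class VelocityHistory:
    """Stacked velocity grids over consecutive frame pairs."""

    times: np.ndarray  # time of the first frame of each pair
    row_px: np.ndarray
    col_px: np.ndarray
    u: np.ndarray  # (n_pairs, rows, cols)
    v: np.ndarray
    valid: np.ndarray
    frame_period: float

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SurfaceTrace:
    """Horizontal velocity at the surface-adjacent, laterally central node."""

    times: np.ndarray
    u: np.ndarray
    valid: np.ndarray


def clahe(image: np.ndarray, tiles: int = 8, clip: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, 0-255 output."""
    image = np.asarray(image)
    h, w = image.shape
    if tiles > min(h, w):
        raise PivError("tile grid larger than image")
    if image.std() == 0:
        return image.astype(float)
    kernel = (max(h // tiles, 1), max(w // tiles, 1))
    eq = equalize_adapthist(image.astype(np.uint8), kernel_size=kernel, clip_limit=clip)
    return eq * 255.0


def anchor_roi(
    table: ContourTable,
    spec: RoiSpec,
    frame_shape: tuple[int, int],
    frame_index: int = 0,
) -> RoiPlacement:
    """Place the ROI: horizontally centered, top edge at the median surface
    depth of ``frame_index`` over the central half of stations."""
    depth_img, width_img = frame_shape
    depths = table.depth_px[frame_index]
    n = depths.size
    central = depths[n // 4 : (3 * n) // 4]
    row0 = int(round(float(np.median(central))))
    col0 = (width_img - spec.width) // 2
    if col0 < 0 or row0 < 0 or row0 + spec.height > depth_img:
        raise PivError(
            f"ROI ({spec.height}x{spec.width} at row {row0}) exceeds the {depth_img}x{width_img} frame"
        )
    return RoiPlacement(row0, col0, spec.height, spec.width)


def _starts(extent: int, window: int, step: int) -> np.ndarray:
    n = (extent - window) // step + 1
    if n < 1:
        raise PivError(f"window {window} exceeds ROI extent {extent}")
    return np.arange(n) * step


def grid_shape(roi: RoiSpec, config: PivConfig) -> tuple[int, int]:
    """(n_rows, n_cols) of the final interrogation grid."""
    w = config.pass_windows[-1]
    step = int(round(w * (1.0 - config.overlap_fraction)))
    return len(_starts(roi.height, w, step)), len(_starts(roi.width, w, step))


def correlate_pair(window_a: np.ndarray, window_b: np.ndarray):
    """FFT cross-correlation of mean-subtracted windows.

    Windows are zero-padded to twice their size (linear, not circular,
    correlation) and each lag is normalized by its overlap area; without
    this the triangular overlap taper biases the peak toward zero lag by a
    few percent of the displacement.  The returned n x n surface covers
    lags up to +/- n/2 with zero displacement at (n//2, n//2); ``ok`` is
    False for zero-variance windows.
    """
    a = np.asarray(window_a, dtype=float)
    b = np.asarray(window_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise PivError("windows must be equal and square")
    a = a - a.mean()
    b = b - b.mean()
    if a.std() == 0 or b.std() == 0:
        return np.zeros_like(a), False
    n = a.shape[0]
    fa = np.fft.rfft2(a, s=(2 * n, 2 * n))
    fb = np.fft.rfft2(b, s=(2 * n, 2 * n))
    full = np.fft.fftshift(np.fft.irfft2(np.conj(fa) * fb, s=(2 * n, 2 * n)).real)
    # lag grid of the shifted 2n array: index n is zero lag
    lags = np.arange(2 * n) - n
    counts = np.maximum(n - np.abs(lags), 1).astype(float)
    full = full / (counts[:, None] * counts[None, :])
    lo, hi = n - n // 2, n + n // 2
    return full[lo:hi, lo:hi], True


def _peak_ratio(corr: np.ndarray, radius: int = 5) -> float:
    """Primary-to-secondary peak ratio.

    The exclusion zone around the primary peak must exceed the speckle
    correlation length, or the ratio merely samples the peak's shoulder.
    """
    flat = int(np.argmax(corr))
    i, j = np.unravel_index(flat, corr.shape)
    first = corr[i, j]
    masked = corr.copy()
    masked[max(i - radius, 0) : i + radius + 1, max(j - radius, 0) : j + radius + 1] = -np.inf
    second = masked.max()
    if not np.isfinite(second) or second <= 0:
        return np.inf if first > 0 else 0.0
    return float(first / second)


def subpixel_peak(corr: np.ndarray) -> tuple[float, float, bool]:
    """Integer peak plus 3-point Gaussian (or parabolic fallback) refinement.

    Returns (dv, du, ok) displacement of the second window relative to the
    first; ``ok`` is False when the peak touches the correlation border.
    """
    corr = np.asarray(corr, dtype=float)
    n0, n1 = corr.shape
    i, j = np.unravel_index(int(np.argmax(corr)), corr.shape)
    if i == 0 or j == 0 or i == n0 - 1 or j == n1 - 1:
        return float(i - n0 // 2), float(j - n1 // 2), False

    def _refine(cm: float, c0: float, cp: float) -> float:
        if cm > 0 and c0 > 0 and cp > 0 and c0 >= cm and c0 >= cp:
            denom = 2.0 * np.log(cm) - 4.0 * np.log(c0) + 2.0 * np.log(cp)
            if denom < -1e-12:
                return float((np.log(cm) - np.log(cp)) / denom)
        denom = 2.0 * cm - 4.0 * c0 + 2.0 * cp  # parabolic fallback
        if denom < -1e-12:
            return float((cm - cp) / denom)
        return 0.0

    dv = _refine(corr[i - 1, j], corr[i, j], corr[i + 1, j])
    du = _refine(corr[i, j - 1], corr[i, j], corr[i, j + 1])
    dv = float(np.clip(dv, -1.0, 1.0))
    du = float(np.clip(du, -1.0, 1.0))
    return (i - n0 // 2) + dv, (j - n1 // 2) + du, True


def _normalized_median_mask(u: np.ndarray, v: np.ndarray, valid: np.ndarray, threshold: float) -> np.ndarray:
    """Westerweel-style universal outlier detection on a vector grid."""
    eps = 0.1
    rows, cols = u.shape
    out = valid.copy()
    for comp in (u, v):
        for r in range(rows):
            for c in range(cols):
                if not out[r, c]:
                    continue
                r0, r1 = max(r - 1, 0), min(r + 2, rows)
                c0, c1 = max(c - 1, 0), min(c + 2, cols)
                neigh = comp[r0:r1, c0:c1].ravel()
                mask = valid[r0:r1, c0:c1].ravel().copy()
                center = (r - r0) * (c1 - c0) + (c - c0)
                mask[center] = False
                vals = neigh[mask]
                if vals.size < 3:
                    continue
                med = np.median(vals)
                # mean |residual| rather than median: with few neighbour rows
                # a coherent gradient makes the median residual collapse to
                # zero and every vector would be flagged
                resid = np.mean(np.abs(vals - med))
                if np.abs(comp[r, c] - med) / (resid + eps) > threshold:
                    out[r, c] = False
    return out


def _infill(u: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid nodes by the local mean of valid neighbours."""
    u = u.copy()
    hole = ~valid
    if not hole.any():
        return u
    good = valid.copy()
    for _ in range(u.size):
        if good.all():
            break
        filled_any = False
        nxt_u = u.copy()
        nxt_good = good.copy()
        rows, cols = u.shape
        for r, c in zip(*np.where(~good)):
            r0, r1 = max(r - 1, 0), min(r + 2, rows)
            c0, c1 = max(c - 1, 0), min(c + 2, cols)
            m = good[r0:r1, c0:c1]
            if m.any():
                nxt_u[r, c] = u[r0:r1, c0:c1][m].mean()
                nxt_good[r, c] = True
                filled_any = True
        u, good = nxt_u, nxt_good
        if not filled_any:
            u[~good] = 0.0
            break
    return u


def _single_pass(roi_a: np.ndarray, roi_b: np.ndarray, window: int, step: int, config: PivConfig):
    r_starts = _starts(roi_a.shape[0], window, step)
    c_starts = _starts(roi_a.shape[1], window, step)
    u = np.zeros((r_starts.size, c_starts.size))
    v = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)
    for ri, r0 in enumerate(r_starts):
        for ci, c0 in enumerate(c_starts):
            wa = roi_a[r0 : r0 + window, c0 : c0 + window]
            wb = roi_b[r0 : r0 + window, c0 : c0 + window]
            corr, ok = correlate_pair(wa, wb)
            if not ok:
                continue
            dv, du, ok = subpixel_peak(corr)
            if not ok:
                continue
            v[ri, ci] = dv
            u[ri, ci] = du
            valid[ri, ci] = _peak_ratio(corr, config.peak_exclusion_radius) >= config.peak_ratio_min
    valid = _normalized_median_mask(u, v, valid, config.norm_median_max)
    rows = r_starts + window / 2.0 - 0.5
    cols = c_starts + window / 2.0 - 0.5
    return rows, cols, _infill(u, valid), _infill(v, valid), valid


def _interp_field(rows, cols, values, q_rows, q_cols) -> np.ndarray:
    """Bilinear interpolation of a node field, extrapolating at the edges."""
    if rows.size == 1 and cols.size == 1:
        return np.full(np.broadcast_shapes(np.shape(q_rows), np.shape(q_cols)), values[0, 0])
    if rows.size == 1:
        return np.interp(q_cols, cols, values[0, :]) * np.ones_like(np.asarray(q_rows, dtype=float))
    if cols.size == 1:
        return np.interp(q_rows, rows, values[:, 0]) * np.ones_like(np.asarray(q_cols, dtype=float))
    rgi = RegularGridInterpolator((rows, cols), values, method="linear", bounds_error=False, fill_value=None)
    pts = np.stack([np.asarray(q_rows, dtype=float), np.asarray(q_cols, dtype=float)], axis=-1)
    return rgi(pts)


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    placement: RoiPlacement,
    config: PivConfig = PivConfig(),
) -> VelocityGrid:
    """Two-pass window-deformation PIV on one frame pair.

    Pass 1 estimates a predictor field at the coarse windows; frame_b's ROI
    is bilinearly warped back by the interpolated predictor before pass 2,
    whose correlation yields a correction added to the predictor.
    """
    if frame_a.shape != frame_b.shape:
        raise PivError("frames must share a shape")
    roi_a = placement.crop(np.asarray(frame_a, dtype=float))
    roi_b = placement.crop(np.asarray(frame_b, dtype=float))

    win1 = config.pass_windows[0]
    step1 = int(round(win1 * (1.0 - config.overlap_fraction)))
    rows1, cols1, u1, v1, _ = _single_pass(roi_a, roi_b, win1, step1, config)

    win2 = config.pass_windows[-1]
    step2 = int(round(win2 * (1.0 - config.overlap_fraction)))

    rr, cc = np.meshgrid(np.arange(roi_a.shape[0]), np.arange(roi_a.shape[1]), indexing="ij")
    u_dense = _interp_field(rows1, cols1, u1, rr, cc)
    v_dense = _interp_field(rows1, cols1, v1, rr, cc)
    warped_b = map_coordinates(roi_b, [rr + v_dense, cc + u_dense], order=1, mode="nearest")

    rows2, cols2, du, dv, valid = _single_pass(roi_a, warped_b, win2, step2, config)
    u_pred = _interp_field(rows1, cols1, u1, *np.meshgrid(rows2, cols2, indexing="ij"))
    v_pred = _interp_field(rows1, cols1, v1, *np.meshgrid(rows2, cols2, indexing="ij"))
    u = u_pred + du
    v = v_pred + dv
    valid = _normalized_median_mask(u, v, valid, config.norm_median_max)
    return VelocityGrid(rows2, cols2, _infill(u, valid), _infill(v, valid), valid)


def piv_sequence(
    stack: FrameStack,
    spec: RoiSpec = RoiSpec(),
    config: PivConfig = PivConfig(),
    t_start: float = 10.0,
    t_end: float = 22.0,
    table: ContourTable | None = None,
    placement: RoiPlacement | None = None,
) -> VelocityHistory:
    """PIV over consecutive CLAHE-equalized frame pairs within [t_start, t_end).

    The ROI is anchored once, at the first analyzed frame, from the tracked
    contour (or supplied explicitly), so vertical node coordinates read as
    distance below the dorsal surface throughout the window.
    """
    times = stack.times
    ks = [k for k in range(len(stack) - 1) if t_start <= times[k] < t_end]
    if not ks:
        raise PivError("no frame pairs inside the analysis window")

    if placement is None:
        if table is None:
            raise PivError("either a contour table or an explicit ROI placement is required")
        placement = anchor_roi(table, spec, stack.frame_shape, frame_index=ks[0])

    grids: list[VelocityGrid] = []
    prev_k = None
    prev_eq = None
    for k in ks:
        eq_a = prev_eq if prev_k == k else clahe(stack.frames[k], config.clahe_tiles, config.clahe_clip)
        eq_b = clahe(stack.frames[k + 1], config.clahe_tiles, config.clahe_clip)
        grids.append(piv_pair(eq_a, eq_b, placement, config))
        prev_k, prev_eq = k + 1, eq_b

    return VelocityHistory(
        times=times[ks],
        row_px=grids[0].row_px,
        col_px=grids[0].col_px,
        u=np.stack([g.u for g in grids]),
        v=np.stack([g.v for g in grids]),
        valid=np.stack([g.valid for g in grids]),
        frame_period=1.0 / stack.frame_rate,
    )


def surface_trace(history: VelocityHistory) -> SurfaceTrace:
    """u(t) at the top-row (surface-adjacent), laterally central node."""
    if len(history) == 0:
        raise PivError("empty history")
    col = history.col_px.size // 2
    return SurfaceTrace(
        times=history.times,
        u=history.u[:, 0, col].copy(),
        valid=history.valid[:, 0, col].copy(),
    )


def depth_profile_map(history: VelocityHistory) -> np.ndarray:
    """(ROI rows x time) laterally averaged u; NaN where a row has no valid node."""
    if len(history) == 0:
        raise PivError("empty history")
    sums = np.where(history.valid, history.u, 0.0).sum(axis=2)
    counts = history.valid.sum(axis=2)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out.T
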