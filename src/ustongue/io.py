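"""File interchange: frame stacks (multi-page TIFF / PNG directories with a
JSON metadata sidecar), CSV tables, figures, and run manifests."""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .contour import ContourTable
from .phantom import FrameStack
from .piv import VelocityHistory
from .protocol import ForceTrace

__all__ = [
    "read_stack",
    "write_stack",
    "write_tables",
    "contour_table_frame",
    "velocity_history_frame",
    "force_trace_frame",
]

_META_KEYS = ("frame_rate", "pixels_per_mm")


class IOError_(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "metadata.json"
    return path.with_suffix(path.suffix + ".meta.json")


def _read_metadata(path: Path) -> dict:
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise IOError_(
            f"missing metadata sidecar {meta_path.name}; required keys: {', '.join(_META_KEYS)}"
        )
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise IOError_(f"metadata sidecar lacks required key(s): {', '.join(missing)}")
    return meta


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page 8-bit TIFF with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"frame_rate": stack.frame_rate, "pixels_per_mm": stack.pixels_per_mm})
    )
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF or a directory of numbered PNG frames."""
    path = Path(path)
    meta = _read_metadata(path)
    if path.is_dir():
        frames = _read_png_dir(path)
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if frames.dtype != np.uint8:
        raise IOError_(
            f"expected 8-bit frames, got {frames.dtype}; convert the stack to uint8 first"
        )
    return FrameStack(frames, float(meta["frame_rate"]), float(meta["pixels_per_mm"]))


def _read_png_dir(path: Path) -> np.ndarray:
    files = sorted(p for p in path.glob("*.png"))
    if not files:
        raise IOError_(f"no PNG frames found in {path}")
    indices = []
    for p in files:
        m = re.search(r"(\d+)", p.stem)
        if not m:
            raise IOError_(f"frame file {p.name} has no numeric index")
        indices.append(int(m.group(1)))
    order = np.argsort(indices)
    indices = [indices[i] for i in order]
    files = [files[i] for i in order]
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))[0]
        raise IOError_(f"gap in frame numbering: missing index {missing}")
    frames = [iio.imread(p) for p in files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise IOError_(f"mixed frame shapes: {sorted(shapes)}")
    return np.stack(frames)


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def contour_table_frame(table: ContourTable, view: str = "px") -> pd.DataFrame:
    values = {"px": table.depth_px, "mm": table.depth_mm, "tof": table.tof_us}[view]
    df = pd.DataFrame(values, columns=[f"station_{i + 1}" for i in range(values.shape[1])])
    df.insert(0, "time_s", table.times)
    return df


def velocity_history_frame(history: VelocityHistory) -> pd.DataFrame:
    n_t, n_r, n_c = history.u.shape
    tt, rr, cc = np.meshgrid(np.arange(n_t), np.arange(n_r), np.arange(n_c), indexing="ij")
    return pd.DataFrame(
        {
            "time_s": history.times[tt.ravel()],
            "row": rr.ravel(),
            "col": cc.ravel(),
            "row_px": history.row_px[rr.ravel()],
            "col_px": history.col_px[cc.ravel()],
            "u_px_per_frame": history.u.ravel(),
            "v_px_per_frame": history.v.ravel(),
            "valid": history.valid.ravel(),
        }
    )


def force_trace_frame(trace: ForceTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_s": trace.time, "normal_N": trace.normal_force, "tangential_N": trace.tangential_force}
    )


def write_tables(outputs: dict[str, pd.DataFrame], out_dir: str | Path, manifest: dict | None = None) -> dict[str, Path]:
    """Write CSV outputs plus a JSON run manifest; returns written paths."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError_(f"output directory {out_dir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    for name, df in outputs.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        written[name] = p
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest or {}, indent=2, sort_keys=True))
    written["manifest"] = manifest_path
    return written
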