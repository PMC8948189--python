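"""ROI imaging: tile planning, z-stacks, and compression-based autofocus.

The line-scan geometry fixes the field of view to a 769 µm-wide strip, so
an ROI is imaged as a series of x-offset scan tiles. Focus is found
without a dedicated sensor: frames are JPEG-compressed and the encoded
byte count — which grows with sharp image features — serves as the
sharpness score. A quadratic is fitted to score versus objective position
and its argmax is the per-FOV optimum; the ROI optimum is the median over
several FOVs, which tolerates FOVs that land on empty glass.

Four routines trade focus quality against time: ``full`` and ``partial``
refocus every cycle (on the whole ROI or only its center x-tile);
``full_once`` and ``partial_once`` reuse the cycle-1 optimum in later
cycles so objective positions stay comparable across cycles.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .protocol import ROI

__all__ = [
    "TilePlan",
    "FocusStack",
    "FocusResult",
    "AutofocusError",
    "plan_tiles",
    "sharpness",
    "fit_focus_curve",
    "autofocus_roi",
    "tile_filename",
    "write_tile",
]

#: Camera field of view width, µm (one scan strip).
FOV_WIDTH_UM = 769.0
#: JPEG encoder settings pinned so sharpness scores are comparable:
#: 12-bit data is converted to 8 bits by a fixed >>4 shift, then encoded
#: at quality 75 with chroma subsampling off.
JPEG_QUALITY = 75
#: FOVs stacked per routine.
N_FOCUS_FOVS = {"full": 5, "full_once": 5, "partial": 3, "partial_once": 3}
#: Minimum interquartile-range contrast for a candidate focus FOV, DN.
CONTRAST_THRESHOLD_DN = 5.0


class AutofocusError(RuntimeError):
    pass


@dataclass(frozen=True)
class TilePlan:
    roi: ROI
    tile_origins: tuple[tuple[float, float], ...]  # (x µm, y µm) per tile
    scan_length_um: float
    n_z: int
    tile_width_um: float


@dataclass(frozen=True)
class FocusStack:
    """Frames acquired while stepping the objective through a FOV."""

    positions_nm: tuple[float, ...]
    frames: tuple[np.ndarray, ...]
    fov_center_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.diff(self.positions_nm)
        if len(self.positions_nm) != len(self.frames):
            raise ValueError("positions and frames differ in length")
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("objective positions must be strictly monotone")


@dataclass(frozen=True)
class FocusResult:
    fov_optima_nm: tuple[float, ...]
    roi_optimum_nm: float
    mode: str
    from_cache: bool = False


def plan_tiles(roi: ROI, fov_width_um: float = FOV_WIDTH_UM,
               overlap_um: float = 0.0, n_z: int | None = None) -> TilePlan:
    """Lay out scan tiles covering an ROI.

    Tiles advance in x by ``fov_width − overlap``; the first origin sits at
    the ROI corner so the corner starts just outside the previous stage
    position and every ROI point falls inside at least one tile. The tile
    count is ``ceil(roi_width / (fov_width − overlap))``.
    """
    if not (fov_width_um > overlap_um >= 0):
        raise ValueError("need fov_width > overlap ≥ 0")
    width_um = roi.width_mm * 1000.0
    height_um = roi.height_mm * 1000.0
    if width_um <= 0 or height_um <= 0:
        raise ValueError("zero-area ROI")
    step = fov_width_um - overlap_um
    n_tiles = math.ceil(width_um / step)
    x0 = roi.x_min * 1000.0
    y0 = roi.y_min * 1000.0
    origins = tuple((x0 + i * step, y0) for i in range(n_tiles))
    return TilePlan(
        roi=roi,
        tile_origins=origins,
        scan_length_um=height_um,
        n_z=n_z if n_z is not None else roi.z_planes,
        tile_width_um=fov_width_um,
    )


def sharpness(frame: np.ndarray) -> int:
    """Sharpness score of a frame: its JPEG-compressed byte count.

    Compression length increases with fine image detail, so sharper frames
    score higher. Deterministic for identical input under the pinned
    encoder settings.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.dtype != np.uint8:
        frame8 = (np.clip(frame, 0, 4095).astype(np.uint16) >> 4).astype(
            np.uint8)
    else:
        frame8 = frame
    buf = io.BytesIO()
    Image.fromarray(frame8, mode="L").save(
        buf, format="JPEG", quality=JPEG_QUALITY, subsampling=0)
    return buf.getbuffer().nbytes


def fit_focus_curve(stack: FocusStack) -> tuple[float, bool]:
    """Locate the objective position of peak sharpness in a focus stack.

    A quadratic is fitted to the top half of the JPEG-size scores as a
    function of objective position; its argmax, constrained to the scanned
    interval, is the per-FOV optimum. Returns ``(optimum_nm, found)``;
    ``found`` is False for flat or monotone profiles with no interior
    peak ("no focus found").
    """
    if len(stack.frames) < 5:
        raise ValueError("need at least 5 frames to fit a focus curve")
    pos = np.asarray(stack.positions_nm, dtype=float)
    scores = np.asarray([sharpness(f) for f in stack.frames], dtype=float)

    if np.ptp(scores) == 0:
        return float(pos[np.argmax(scores)]), False
    peak_idx = int(np.argmax(scores))
    if peak_idx in (0, len(scores) - 1):
        # best frame at a boundary: profile is monotone over the scan
        return float(pos[peak_idx]), False

    # fit only the top half of scores: the quadratic approximates the
    # peak, not the tails
    order = np.argsort(scores)[::-1]
    keep = np.sort(order[:max(3, len(scores) // 2)])
    # center positions for conditioning
    p0 = pos[keep].mean()
    coeffs = np.polyfit(pos[keep] - p0, scores[keep], 2)
    a, b, _ = coeffs
    if a >= 0:
        return float(pos[peak_idx]), False
    opt = -b / (2 * a) + p0
    opt = float(np.clip(opt, pos.min(), pos.max()))
    return opt, True


def _rank_fovs(survey: np.ndarray,
               candidates: list[tuple[int, int]],
               fov_px: int, n_select: int) -> list[tuple[int, int]]:
    """Greedy FOV selection maximizing contrast under a pairwise-distance
    constraint.

    Contrast of a candidate is the interquartile range of the survey image
    under its footprint; candidates are taken best-first subject to being
    ≥ 1 FOV width from every already-selected FOV.
    """
    scored = []
    for (r, c) in candidates:
        patch = survey[r:r + fov_px, c:c + fov_px]
        if patch.size == 0:
            continue
        q75, q25 = np.percentile(patch, [75, 25])
        scored.append((q75 - q25, (r, c)))
    scored.sort(key=lambda t: -t[0])
    selected: list[tuple[int, int]] = []
    for contrast, rc in scored:
        if contrast < CONTRAST_THRESHOLD_DN:
            continue
        if all(math.hypot(rc[0] - s[0], rc[1] - s[1]) >= fov_px
               for s in selected):
            selected.append(rc)
        if len(selected) == n_select:
            break
    return selected


def autofocus_roi(roi: ROI, mode: str, cycle_index: int,
                  cache: dict, survey: np.ndarray,
                  stack_provider, fov_px: int = 64,
                  manual_chooser=None) -> FocusResult:
    """Find the optimal objective position for an ROI.

    Parameters
    ----------
    mode
        ``full`` / ``partial`` recompute every cycle; ``full_once`` /
        ``partial_once`` reuse the cycle-1 optimum from ``cache``;
        ``manual`` delegates to ``manual_chooser(stack) -> position``.
    cycle_index
        1-based imaging cycle.
    cache
        Mutable dict keyed by ROI label holding cycle-1 results.
    survey
        Out-of-focus survey image of the ROI (row ↔ y, col ↔ x).
    stack_provider
        Callback ``(row, col) -> FocusStack`` producing an objective stack
        at the FOV whose top-left survey pixel is (row, col).
    fov_px
        FOV footprint on the survey raster, pixels.

    The partial routines restrict candidate FOVs to the single tile at the
    center of the ROI in x; candidates are ranked by interquartile-range
    contrast with a pairwise minimum separation of one FOV width, the top
    ones are stacked, and the ROI optimum is the median of the per-FOV
    optima.
    """
    if mode not in ("full", "partial", "full_once", "partial_once", "manual"):
        raise ValueError(f"unknown autofocus mode {mode!r}")

    if mode in ("full_once", "partial_once") and cycle_index > 1:
        if roi.label in cache:
            prev = cache[roi.label]
            return FocusResult(prev.fov_optima_nm, prev.roi_optimum_nm,
                               mode, from_cache=True)
        # no cached cycle-1 result: fall through and compute one

    if mode == "manual":
        if manual_chooser is None:
            raise AutofocusError("manual mode needs a chooser callback")
        h, w = survey.shape
        stack = stack_provider((h - fov_px) // 2, (w - fov_px) // 2)
        pos = float(manual_chooser(stack))
        result = FocusResult((pos,), pos, mode)
        cache[roi.label] = result
        return result

    h, w = survey.shape
    n_select = N_FOCUS_FOVS[mode]
    if mode.startswith("partial"):
        # single tile at the center of the ROI in x
        n_tiles = max(1, math.ceil(w / fov_px))
        center_tile = n_tiles // 2
        c_lo = center_tile * fov_px
        c_hi = min(w, c_lo + fov_px)
        cols = range(c_lo, max(c_lo + 1, c_hi - fov_px + 1), fov_px)
    else:
        cols = range(0, max(1, w - fov_px + 1), fov_px)
    rows = range(0, max(1, h - fov_px + 1), fov_px)
    candidates = [(r, c) for r in rows for c in cols]

    selected = _rank_fovs(survey, candidates, fov_px, n_select)
    if not selected:
        raise AutofocusError(
            "no FOV passes the contrast filter; consider manual focus mode")

    optima = []
    for rc in selected:
        stack = stack_provider(*rc)
        opt, found = fit_focus_curve(stack)
        if found:
            optima.append(opt)
    if not optima:
        raise AutofocusError(
            "no focus found in any stacked FOV; consider manual focus mode")
    roi_opt = float(np.median(optima))
    result = FocusResult(tuple(optima), roi_opt, mode)
    if cycle_index == 1 or roi.label not in cache:
        cache[roi.label] = result
    return result


# ---------------------------------------------------------------------------
# Tile output

def tile_filename(cycle: int, channel_nm: int, tile: int, z: int) -> str:
    return f"c{cycle}_ch{channel_nm}_x{tile}_z{z}.tif"


def write_tile(path, tile: np.ndarray) -> None:
    """Write a 12-bit-in-16-bit tile as TIFF."""
    import tifffile

    tile = np.asarray(tile)
    if tile.dtype != np.uint16:
        tile = np.clip(tile, 0, 4095).astype(np.uint16)
    tifffile.imwrite(str(path), tile)
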