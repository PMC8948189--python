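"""Raw-image corrections.

Three artifacts of the line-scan optics are corrected here:

* **dark-group offsets** — each camera reads its 2048-pixel line through
  8 groups of 256 pixels, and each group registers a slightly different
  mean dark value ``d_px[g]``; the additive offset
  ``mean_g(d_px) − d_px[g]`` flattens the background across a tile,
* **chromatic shifts** — fixed integer-pixel translations between the four
  detection channels, measured once from bead images and supplied as
  configuration,
* **cycle shifts** — rigid drift of the sample between staining cycles,
  estimated by phase cross-correlation of each cycle's 610 nm image
  against the pre-stain autofluorescence reference, on a central window
  only (2.3 mm² by default) to bound computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = [
    "DarkModel",
    "ShiftEstimate",
    "estimate_dark_offsets",
    "apply_dark_correction",
    "register_channels",
    "shift_image",
    "register_cycles",
]

N_GROUPS = 8
GROUP_WIDTH = 256
#: Area of the central registration window, mm².
CENTRAL_WINDOW_MM2 = 2.3
#: Camera pixel pitch at the sample, µm (769 µm FOV across 2048 px).
PIXEL_PITCH_UM = 769.0 / 2048
#: Pearson correlation (reference vs shifted image on their overlap)
#: below which a cycle-shift estimate is flagged low-confidence.
CONFIDENCE_THRESHOLD = 0.2


@dataclass(frozen=True)
class DarkModel:
    """Per-pixel-group dark levels and the offsets that equalize them.

    ``d_px[g]`` is the mean dark value of readout group ``g``;
    ``offset[g] = mean_g(d_px) − d_px[g]``, so per camera the offsets sum
    to zero (within rounding).
    """

    camera: int
    d_px: tuple[float, ...]

    @property
    def offsets(self) -> np.ndarray:
        d = np.asarray(self.d_px, dtype=float)
        return d.mean() - d

    def to_tsv(self) -> str:
        lines = ["group\td_px\toffset"]
        for g, (d, o) in enumerate(zip(self.d_px, self.offsets)):
            lines.append(f"{g}\t{d:.4f}\t{o:.4f}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ShiftEstimate:
    """A rigid (dy, dx) translation in pixels, possibly subpixel."""

    dy: float
    dx: float
    source: str                 # "chromatic_manual" | "cycle_phase_corr"
    reference: str = ""
    confident: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dy) and math.isfinite(self.dx)):
            raise ValueError("shift must be finite")


def _group_means(frame: np.ndarray) -> np.ndarray:
    if frame.shape[-1] % (N_GROUPS * GROUP_WIDTH) or \
            frame.shape[-1] // GROUP_WIDTH != N_GROUPS:
        raise ValueError(
            f"frame width {frame.shape[-1]} does not divide into "
            f"{N_GROUPS} groups of {GROUP_WIDTH} pixels")
    return frame.reshape(-1, N_GROUPS, GROUP_WIDTH).mean(axis=(0, 2))


def estimate_dark_offsets(dark_frames: list[np.ndarray],
                          camera: int = 0) -> DarkModel:
    """Fit a :class:`DarkModel` from dark frames of one camera.

    Each frame must be ``8 × 256 = 2048`` pixels wide; ``d_px[g]`` is the
    mean over all supplied frames of the pixels in group ``g``.
    """
    if not dark_frames:
        raise ValueError("need at least one dark frame")
    means = np.mean([_group_means(np.asarray(f, dtype=float))
                     for f in dark_frames], axis=0)
    return DarkModel(camera=camera, d_px=tuple(float(m) for m in means))


def apply_dark_correction(tile: np.ndarray, model: DarkModel,
                          camera: int | None = None) -> np.ndarray:
    """Add each group's dark offset to its pixels; clip to [0, 4095].

    Within-group contrasts are preserved exactly (a single additive
    constant per group). Raises on a camera mismatch when ``camera`` is
    given.
    """
    if camera is not None and camera != model.camera:
        raise ValueError(
            f"dark model is for camera {model.camera}, tile from {camera}")
    tile = np.asarray(tile, dtype=float)
    _group_means(tile)  # validates width
    per_pixel = np.repeat(model.offsets, GROUP_WIDTH)
    out = tile + per_pixel[None, :]
    return np.clip(np.rint(out), 0, 4095).astype(np.uint16)


def shift_image(image: np.ndarray, dy: int, dx: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Integer-pixel rigid translation.

    Returns ``(shifted, valid_mask)``; pixels carried in from outside the
    frame are 0 and masked invalid. ``shift_image(·, -dy, -dx)`` inverts
    the translation up to the border crop.
    """
    image = np.asarray(image)
    out = np.zeros_like(image)
    mask = np.zeros(image.shape, dtype=bool)
    h, w = image.shape[:2]
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = image[ys_src, xs_src]
    mask[ys_dst, xs_dst] = True
    return out, mask


def register_channels(tiles: dict[int, np.ndarray],
                      shifts: dict[int, ShiftEstimate]
                      ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Rigidly align per-channel tiles by their measured chromatic shifts.

    ``shifts[ch]`` is the translation that maps channel ``ch`` onto the
    reference frame; channels without an entry are treated as (0, 0).
    Returns ``{channel: (aligned, valid_mask)}`` so that pixels correspond
    1–1 across channels; out-of-frame regions are masked.
    """
    out = {}
    for ch, tile in tiles.items():
        s = shifts.get(ch)
        dy, dx = (int(round(s.dy)), int(round(s.dx))) if s else (0, 0)
        out[ch] = shift_image(tile, dy, dx)
    return out


def central_window(image: np.ndarray,
                   window_mm2: float = CENTRAL_WINDOW_MM2,
                   pixel_pitch_um: float = PIXEL_PITCH_UM) -> np.ndarray:
    """Crop the central square window of the given area.

    The window side is ``√area`` converted to pixels via the pixel pitch,
    clipped to the image extent.
    """
    side_px = int(round(math.sqrt(window_mm2) * 1000.0 / pixel_pitch_um))
    h, w = image.shape[:2]
    side_y = min(side_px, h)
    side_x = min(side_px, w)
    r0 = (h - side_y) // 2
    c0 = (w - side_x) // 2
    return image[r0:r0 + side_y, c0:c0 + side_x]


def register_cycles(cycle_images: dict[int, np.ndarray],
                    reference: np.ndarray,
                    upsample_factor: int = 10,
                    window_mm2: float = CENTRAL_WINDOW_MM2,
                    pixel_pitch_um: float = PIXEL_PITCH_UM
                    ) -> dict[int, ShiftEstimate]:
    """Estimate per-cycle rigid shifts against a reference image.

    Phase cross-correlation (subpixel, ×``upsample_factor``) between the
    central window of the reference (typically the pre-stain
    autofluorescence image in the 610 nm channel) and the same window of
    each cycle's image. The returned ``(dy, dx)`` is the measured
    displacement of the cycle image relative to the reference: applying
    ``shift_image(img, -dy, -dx)`` to every channel of that cycle aligns
    it with the reference. Estimates whose post-alignment correlation
    with the reference falls below a confidence threshold are flagged and
    set to (0, 0).
    """
    ref_win = central_window(np.asarray(reference, dtype=float),
                             window_mm2, pixel_pitch_um)
    out: dict[int, ShiftEstimate] = {}
    for cycle, img in cycle_images.items():
        img = np.asarray(img, dtype=float)
        if img.shape != np.asarray(reference).shape:
            raise ValueError(
                f"cycle {cycle} image shape {img.shape} differs from "
                f"reference {np.asarray(reference).shape}")
        win = central_window(img, window_mm2, pixel_pitch_um)
        shift, _, _ = phase_cross_correlation(
            ref_win, win, upsample_factor=upsample_factor,
            normalization=None)
        # phase correlation yields the shift registering the cycle image
        # onto the reference; negate to report the cycle's displacement
        dy, dx = -float(shift[0]), -float(shift[1])
        # confidence: correlation of the reference with the aligned image
        moved, mask = shift_image(win, -int(round(dy)), -int(round(dx)))
        a = ref_win[mask].ravel()
        b = moved[mask].ravel()
        if a.size < 16 or a.std() == 0 or b.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        if r < CONFIDENCE_THRESHOLD:
            out[cycle] = ShiftEstimate(0.0, 0.0, "cycle_phase_corr",
                                       reference=str(cycle), confident=False)
        else:
            out[cycle] = ShiftEstimate(dy, dx, "cycle_phase_corr",
                                       reference=str(cycle), confident=True)
    return out


def shifts_to_tsv(shifts: dict[int, ShiftEstimate]) -> str:
    lines = ["cycle\tdy\tdx\tsource\tconfident"]
    for cycle in sorted(shifts):
        s = shifts[cycle]
        lines.append(f"{cycle}\t{s.dy:.3f}\t{s.dx:.3f}\t{s.source}\t"
                     f"{int(s.confident)}")
    return "\n".join(lines) + "\n"
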