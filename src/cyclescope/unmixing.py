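"""Spectral crosstalk estimation and removal.

Emission from a fluorophore detected in its primary channel (AF532→558 nm,
AF594→610 nm, Cy5→687 nm, AF700→740 nm) partially leaks into the adjacent
channel. With ``D_i`` the source-channel image and ``D_j`` the
contaminated adjacent-channel image, a single leakage coefficient ``x``
describes the mixing and the unmixed image is ``D_j − x·D_i``.

Two estimators of ``x`` are provided:

* **blind** — a non-iterative mutual-information minimization: after
  background subtraction, ``I(D_j − x·D_i ; D_i)`` is evaluated on a grid
  of ``x ∈ [0, 2]`` and the optimum is the minimum of a curve fitted
  around the grid minimum. Needs no reference images.
* **linear** — from singleplex reference images of one fluorophore:
  ``x_l`` is the slope of a line fitted to corresponding pixel
  intensities of ``D_i`` and ``D_j``, weighted by ``D_i`` intensity.

Diagnostics: Pearson correlation of randomly sampled above-background
pixels between channel pairs, before and after unmixing, and per-pixel
channel proportions for singleplex stains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BackgroundModel",
    "MixingEstimate",
    "subtract_background",
    "mutual_information",
    "estimate_leakage_blind",
    "estimate_leakage_linear",
    "unmix",
    "channel_proportions",
    "crosstalk_correlation",
    "PRIMARY_CHANNELS",
    "DEFAULT_LEAKAGE_PAIRS",
]

#: Fluorophore → primary detection channel (nm).
PRIMARY_CHANNELS = {"AF532": 558, "AF594": 610, "Cy5": 687, "AF700": 740}
#: Channel pairs with appreciable spillover (source → target).
DEFAULT_LEAKAGE_PAIRS = ((558, 610), (687, 740))

#: Grid for blind leakage search: 41 evenly spaced points on [0, 2].
X_GRID = np.linspace(0.0, 2.0, 41)
#: Points around the grid minimum used for the quadratic I(x) fit. Three
#: (the bracketing points) makes the refinement a parabolic interpolation
#: of the minimum, which never moves it by more than half a grid step;
#: wider windows drag the fitted argmin around when I(x) is asymmetric
#: about the minimum.
FIT_NEIGHBORHOOD = 3
#: Joint-histogram bins per axis for the mutual-information estimator.
MI_BINS = 64


@dataclass(frozen=True)
class BackgroundModel:
    """Background to subtract before unmixing.

    ``mode_plus_sd`` — a global level equal to the mode of pixel
    intensities plus one standard deviation (used for tissue with low
    autofluorescence); ``reference_image`` — a registered pre-stain
    autofluorescence raster subtracted pixelwise (used for tissue whose
    autofluorescence has structure).
    """

    kind: str                                  # "mode_plus_sd" | "reference_image"
    global_level: float = 0.0
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mode_plus_sd", "reference_image"):
            raise ValueError(f"unknown background kind {self.kind!r}")
        if self.global_level < 0:
            raise ValueError("global_level must be ≥ 0")
        if self.kind == "reference_image" and self.reference is None:
            raise ValueError("reference_image background needs a reference")

    @classmethod
    def from_image(cls, image: np.ndarray) -> "BackgroundModel":
        """Fit the mode-plus-1-SD global level from an image."""
        v = np.asarray(image).ravel()
        vals, counts = np.unique(np.rint(v).astype(np.int64),
                                 return_counts=True)
        mode = float(vals[np.argmax(counts)])
        return cls("mode_plus_sd", global_level=mode + float(np.std(v)))


@dataclass(frozen=True)
class MixingEstimate:
    """Leakage coefficient for an ordered channel pair."""

    source_channel: int
    target_channel: int
    x: float
    method: str                                # "blind" | "linear"
    warning: str = ""

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("leakage coefficient must be ≥ 0")


def subtract_background(D: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """``max(D − level-or-reference, 0)``, as float."""
    D = np.asarray(D, dtype=float)
    if bg.kind == "mode_plus_sd":
        return np.maximum(D - bg.global_level, 0.0)
    ref = np.asarray(bg.reference, dtype=float)
    if ref.shape != D.shape:
        raise ValueError(
            f"reference shape {ref.shape} does not match image {D.shape}; "
            f"register the reference first")
    return np.maximum(D - ref, 0.0)


def mutual_information(Da: np.ndarray, Db: np.ndarray,
                       bins: int = MI_BINS,
                       mask: np.ndarray | None = None) -> float:
    """Mutual information (nats) between two rasters.

    Plug-in estimate from the 2-D joint histogram with ``bins`` equal-width
    bins per axis over each raster's positive-value range. Symmetric and
    ≥ 0 by construction; deterministic given the binning.
    """
    Da = np.asarray(Da, dtype=float)
    Db = np.asarray(Db, dtype=float)
    if Da.shape != Db.shape:
        raise ValueError("rasters must have equal shapes")
    if mask is not None:
        Da, Db = Da[mask], Db[mask]
        if Da.size == 0:
            raise ValueError("mask excludes every pixel")
    a = Da.ravel()
    b = Db.ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(pa, pb)
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def estimate_leakage_blind(Di: np.ndarray, Dj: np.ndarray,
                           x_grid: np.ndarray = X_GRID,
                           bins: int = MI_BINS,
                           source_channel: int = 0,
                           target_channel: int = 0) -> MixingEstimate:
    """Blind leakage estimate by mutual-information minimization.

    Both images must already be background-subtracted. ``I(D_j − x·D_i ;
    D_i)`` is evaluated at every grid point, a quadratic is fitted to the
    points bracketing the grid minimum, and its argmin — constrained to
    the grid range — is the estimate. Non-iterative. If ``I(x)`` is
    monotone over the grid the boundary value is returned with a warning.

    The residual is *not* clipped at zero inside the minimization: the
    structure of over-subtracted (negative) pixels is exactly the signal
    that penalizes too-large ``x``, and discarding it flattens I(x) into
    a plateau that biases the estimate upward. Clipping is applied only
    when the final unmixed image is produced (:func:`unmix`).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size == 0:
        raise ValueError("empty x grid")
    Di = np.asarray(Di, dtype=float)
    Dj = np.asarray(Dj, dtype=float)
    if x_grid.size == 1:
        return MixingEstimate(source_channel, target_channel,
                              float(x_grid[0]), "blind",
                              warning="degenerate single-point grid")

    I = np.array([
        mutual_information(Dj - x * Di, Di, bins=bins)
        for x in x_grid
    ])
    k = int(np.argmin(I))
    if k in (0, x_grid.size - 1):
        msg = ("I(x) is monotone over the searched range; returning the "
               "boundary value")
        warnings.warn(msg, stacklevel=2)
        return MixingEstimate(source_channel, target_channel,
                              float(x_grid[k]), "blind", warning=msg)

    half = FIT_NEIGHBORHOOD // 2
    lo = max(0, k - half)
    hi = min(x_grid.size, k + half + 1)
    xs = x_grid[lo:hi]
    a, b, _ = np.polyfit(xs - xs.mean(), I[lo:hi], 2)
    if a <= 0:
        x_opt = float(x_grid[k])
    else:
        x_opt = float(np.clip(-b / (2 * a) + xs.mean(),
                              x_grid[0], x_grid[-1]))
    return MixingEstimate(source_channel, target_channel, x_opt, "blind")


def estimate_leakage_linear(Di_ref: np.ndarray, Dj_ref: np.ndarray,
                            source_channel: int = 0,
                            target_channel: int = 0) -> MixingEstimate:
    """Linear leakage estimate from singleplex reference images.

    ``x_l`` is the slope of a through-origin line fitted to corresponding
    pixel intensities of the (background-subtracted) source and target
    reference images, weighted by source intensity:

        x_l = Σ w·D_i·D_j / Σ w·D_i²,   w = D_i.

    Exact on noiseless proportional images.
    """
    Di = np.asarray(Di_ref, dtype=float).ravel()
    Dj = np.asarray(Dj_ref, dtype=float).ravel()
    if Di.shape != Dj.shape:
        raise ValueError("reference images must have equal shapes")
    w = Di
    denom = np.sum(w * Di * Di)
    if denom == 0:
        raise ValueError("source reference image is all zero")
    x_l = float(np.sum(w * Di * Dj) / denom)
    return MixingEstimate(source_channel, target_channel,
                          max(x_l, 0.0), "linear")


def unmix(Dj: np.ndarray, Di: np.ndarray, x: float,
          clip_negative: bool = True) -> np.ndarray:
    """Remove leakage: ``D_j − x·D_i``, negatives clipped to 0.

    ``unmix(Dj, Di, 0)`` returns ``Dj`` unchanged (bit-exact).
    """
    if x < 0:
        raise ValueError("leakage coefficient must be ≥ 0")
    Dj = np.asarray(Dj)
    if x == 0:
        return Dj
    out = np.asarray(Dj, dtype=float) - x * np.asarray(Di, dtype=float)
    if clip_negative:
        out = np.maximum(out, 0.0)
    return out


def channel_proportions(stack: np.ndarray, primary_index: int,
                        background_level: float = 0.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel signal proportions across channels for a singleplex stain.

    ``stack`` is ``(n_channels, h, w)`` (or ``(n_pixels, n_channels)``).
    Pixels are kept when their primary-channel intensity exceeds
    ``background_level``; each kept pixel's intensities are divided by
    their sum over channels, so rows sum to 1. Zero-sum pixels are
    excluded. Returns ``(proportions (n_kept, n_channels), kept_mask)``.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 3:
        px = arr.reshape(arr.shape[0], -1).T
    elif arr.ndim == 2:
        px = arr
    else:
        raise ValueError("stack must be (C, H, W) or (N, C)")
    keep = px[:, primary_index] > background_level
    sums = px.sum(axis=1)
    keep &= sums > 0
    props = px[keep] / sums[keep, None]
    return props, keep


def crosstalk_correlation(Di: np.ndarray, Dj: np.ndarray,
                          background_level: float = 0.0,
                          n_sample: int = 10_000,
                          rng_seed: int | None = None) -> float:
    """Pearson r between source- and target-channel intensities.

    Sampled at ``n_sample`` random pixels above background in the source
    (primary) channel, with corresponding pixels taken from the adjacent
    channel. Falls back to all qualifying pixels (with a warning) when
    fewer than ``n_sample`` are available.
    """
    Di = np.asarray(Di, dtype=float).ravel()
    Dj = np.asarray(Dj, dtype=float).ravel()
    if Di.shape != Dj.shape:
        raise ValueError("images must have equal shapes")
    idx = np.flatnonzero(Di > background_level)
    if idx.size == 0:
        raise ValueError("no pixels above background in the primary channel")
    rng = np.random.default_rng(rng_seed)
    if idx.size < n_sample:
        warnings.warn(
            f"only {idx.size} pixels above background; sampling all",
            stacklevel=2)
        sample = idx
    else:
        sample = rng.choice(idx, size=n_sample, replace=False)
    r, _ = stats.pearsonr(Di[sample], Dj[sample])
    return float(r)


def mixing_table_tsv(estimates: list[MixingEstimate]) -> str:
    """Serialize mixing estimates as a small tab-separated table."""
    lines = ["source_nm\ttarget_nm\tx\tmethod\twarning"]
    for e in estimates:
        lines.append(f"{e.source_channel}\t{e.target_channel}\t"
                     f"{e.x:.4f}\t{e.method}\t{e.warning}")
    return "\n".join(lines) + "\n"
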