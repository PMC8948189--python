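"""Post-processing: histogram rescaling, region histograms, domain maps.

Raw tiles carry 12-bit data in 16-bit containers; for display they are
rescaled to the full 16-bit range. Annotated-region intensity histograms
(log2 density over randomly sampled pixels) compare staining between
anatomical regions and samples. K-means clustering of per-pixel channel
vectors on a downsampled raster turns a high-plex stack into a
tissue-domain map in which each cluster label marks a recurring channel
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rescale
from sklearn.cluster import KMeans

__all__ = [
    "RegionAnnotation",
    "DomainMap",
    "rescale_12to16",
    "adjust_histogram",
    "region_histogram",
    "kmeans_domains",
]


@dataclass(frozen=True)
class RegionAnnotation:
    """A labeled anatomical region (e.g. ventral_horn) as a boolean mask."""

    label: str
    mask: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise ValueError(f"annotation {self.label!r} has an empty mask")


@dataclass(frozen=True)
class DomainMap:
    """Per-pixel cluster labels over a (downsampled) raster."""

    labels: np.ndarray
    k: int
    channel_count: int
    downsample: float

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("label values must lie in 0..k-1")

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.labels.astype(np.uint8))


def rescale_12to16(tile: np.ndarray, full_range: bool = False) -> np.ndarray:
    """Rescale 12-bit data to 16-bit encoding.

    Default is the ×16 bit shift (4095 → 65520); ``full_range=True`` maps
    linearly onto 0..65535 (4095 → 65535). Both are monotone. Raises when
    any value exceeds the 12-bit maximum.
    """
    tile = np.asarray(tile)
    if tile.max(initial=0) > 4095:
        raise ValueError("input exceeds 12-bit range (max 4095)")
    if full_range:
        out = np.rint(tile.astype(float) * (65535.0 / 4095.0))
    else:
        out = tile.astype(np.uint32) << 4
    return np.clip(out, 0, 65535).astype(np.uint16)


def adjust_histogram(tile: np.ndarray, mode: str = "linear",
                     vmin: float = 0.0, vmax: float | None = None,
                     gamma: float = 1.0) -> np.ndarray:
    """Display-only histogram adjustment, linear windowing or gamma.

    Values are mapped to [0, 1]: linear — ``(v − vmin)/(vmax − vmin)``
    clipped; gamma — the linear map followed by ``v**gamma``. Identity at
    full range with ``gamma=1``. Apply the same parameters to every tile
    of an antibody within an experiment so intensities stay comparable.
    """
    if mode not in ("linear", "gamma"):
        raise ValueError(f"unknown adjustment mode {mode!r}")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    tile = np.asarray(tile, dtype=float)
    if vmax is None:
        vmax = float(tile.max()) if tile.max() > vmin else vmin + 1.0
    out = np.clip((tile - vmin) / (vmax - vmin), 0.0, 1.0)
    if mode == "gamma":
        out = out ** gamma
    return out


def region_histogram(image: np.ndarray,
                     annotations: list[RegionAnnotation],
                     n_pixels: int = 1_000_000,
                     bins: int = 256,
                     rng_seed: int | None = None
                     ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Log2 pixel-intensity densities for annotated regions.

    Samples ``n_pixels`` pixels per region (with replacement when the
    region is smaller), takes ``log2(intensity)`` with zeros clamped to
    intensity 1, and returns ``{label: (bin_edges, density)}``. Seeded and
    invariant to mask pixel ordering.
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(rng_seed)
    out = {}
    for ann in annotations:
        vals = image[ann.mask]
        if vals.size == 0:
            raise ValueError(f"annotation {ann.label!r} selects no pixels")
        sample = rng.choice(vals, size=n_pixels,
                            replace=vals.size < n_pixels)
        logv = np.log2(np.maximum(sample, 1.0))
        density, edges = np.histogram(logv, bins=bins, range=(0.0, 16.0),
                                      density=True)
        out[ann.label] = (edges, density)
    return out


def histogram_table_tsv(hists: dict[str, tuple[np.ndarray, np.ndarray]]
                        ) -> str:
    """Serialize region histograms as a (region, bin, density) TSV."""
    lines = ["region\tbin_log2\tdensity"]
    for label, (edges, density) in hists.items():
        centers = (edges[:-1] + edges[1:]) / 2
        for c, d in zip(centers, density):
            lines.append(f"{label}\t{c:.4f}\t{d:.6g}")
    return "\n".join(lines) + "\n"


def plot_region_histograms(hists: dict[str, tuple[np.ndarray, np.ndarray]],
                           path=None):
    """Density plot of log2 pixel intensity per region; saves to ``path``
    when given, otherwise returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, (edges, density) in hists.items():
        centers = (edges[:-1] + edges[1:]) / 2
        ax.plot(centers, density, label=label)
    ax.set_xlabel(r"$\log_2$(pixel intensity)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path), dpi=150)
        plt.close(fig)
        return None
    return fig


def kmeans_domains(stack: np.ndarray, k: int = 7,
                   downsample: float = 0.25,
                   rng_seed: int | None = 0) -> DomainMap:
    """Cluster per-pixel channel vectors into tissue domains.

    The multichannel stack ``(C, H, W)`` — registered across channels and
    cycles — is downsampled to ``downsample`` of raw linear resolution to
    smooth pixel-scale registration defects, then k-means (k-means++
    init, fixed seed) partitions the channel vectors; every downsampled
    pixel receives a label in 0..k−1. Defaults: k = 7, 25% resolution.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (C, H, W)")
    if not (0 < downsample <= 1):
        raise ValueError("downsample must be in (0, 1]")
    if downsample < 1:
        small = np.stack([
            rescale(ch, downsample, anti_aliasing=True, preserve_range=True)
            for ch in stack
        ])
    else:
        small = stack
    c, h, w = small.shape
    X = small.reshape(c, -1).T
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(
            f"fewer than k={k} distinct pixel vectors; cannot cluster")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=rng_seed)
    labels = km.fit_predict(X).reshape(h, w)
    return DomainMap(labels=labels, k=k, channel_count=c,
                     downsample=downsample)
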