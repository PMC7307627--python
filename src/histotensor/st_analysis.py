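"""Structure-tensor (ST) anisotropy analysis of stained-section photomicrographs.

The local orientation and coherence of a fibrous texture (e.g. myelinated
axons in a gold-chloride-stained section) are summarised by the 2D structure
tensor: the outer product of the image gradient, aggregated over a window.
Its eigen-structure gives the dominant orientation and an anisotropy index

    AI = (lam1 - lam2) / (lam1 + lam2)  in [0, 1],

the 2D analogue of the fractional anisotropy used in diffusion MRI: 0 for
isotropic texture, 1 for a perfectly coherent one.

Gradients are computed by convolution with the directional derivatives of a
sampled 2D Gaussian (default kernel 11 px, sigma 3 px); pixelwise tensors are
then summed either over non-overlapping square tiles (default, 128 px) or in
a sliding box window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "HistoImage",
    "STConfig",
    "STField",
    "gaussian_derivative_kernels",
    "gaussian_derivatives",
    "structure_tensor_field",
    "anisotropy_index",
    "roi_ai",
    "analyze_image",
    "to_grayscale",
]

#: default acquisition resolution, um^2 per pixel
DEFAULT_PIXEL_AREA = 0.013

# ITU-R BT.709 luminance weights, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to luminance; pass grayscale through unchanged."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[-1] == 3:
        return pixels @ _LUMA
    raise ValueError(f"expected 2D grayscale or HxWx3 RGB, got shape {pixels.shape}")


@dataclass
class HistoImage:
    """A stained-section photomicrograph with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D grayscale intensities in [0, 1] or an HxWx3 RGB array.
    pixel_area : float
        Area of one pixel in um^2 (default 0.013, a typical high-resolution
        light-microscope setting).
    stain : {"myelin", "nissl", "other"}
    """

    pixels: np.ndarray
    pixel_area: float = DEFAULT_PIXEL_AREA
    stain: Literal["myelin", "nissl", "other"] = "other"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("image must be 2D grayscale or HxWx3 RGB")

    @property
    def gray(self) -> np.ndarray:
        return to_grayscale(self.pixels)

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass
class STConfig:
    """Structure-tensor analysis parameters.

    deriv_kernel_size / deriv_sigma control the Gaussian-derivative filters
    (pixels); window is the tensor aggregation window (pixels); aggregation
    selects non-overlapping tiles (default) or a per-pixel sliding box sum.
    """

    deriv_kernel_size: int = 11
    deriv_sigma: float = 3.0
    window: int = 128
    aggregation: Literal["tiled", "sliding"] = "tiled"

    def __post_init__(self) -> None:
        if self.deriv_kernel_size < 3 or self.deriv_kernel_size % 2 == 0:
            raise ValueError("deriv_kernel_size must be odd and >= 3")
        if self.deriv_sigma <= 0:
            raise ValueError("deriv_sigma must be positive")
        if self.window < self.deriv_kernel_size:
            raise ValueError("window must be >= deriv_kernel_size")
        if self.aggregation not in ("tiled", "sliding"):
            raise ValueError("aggregation must be 'tiled' or 'sliding'")


@dataclass
class STField:
    """Aggregated structure tensors and derived maps.

    All arrays share one shape: the tile grid (tiled mode) or the image
    (sliding mode). Eigenvalues satisfy lam1 >= lam2 >= 0; orientation is the
    direction of the dominant eigenvector in radians, wrapped to [0, pi).
    """

    jxx: np.ndarray
    jxy: np.ndarray
    jyy: np.ndarray
    lam1: np.ndarray = field(init=False)
    lam2: np.ndarray = field(init=False)
    orientation: np.ndarray = field(init=False)
    ai_map: np.ndarray = field(init=False)
    aggregation: str = "tiled"
    window: int = 128

    def __post_init__(self) -> None:
        tr = self.jxx + self.jyy
        half_diff = 0.5 * (self.jxx - self.jyy)
        disc = np.sqrt(half_diff**2 + self.jxy**2)
        self.lam1 = 0.5 * tr + disc
        self.lam2 = np.maximum(0.5 * tr - disc, 0.0)  # clip tiny negative rounding
        # texture (fiber) orientation: the direction of least intensity
        # change, i.e. the minor eigenvector; perpendicular to the dominant
        # gradient direction given by 0.5*atan2(2Jxy, Jxx - Jyy)
        self.orientation = np.mod(
            0.5 * np.arctan2(2 * self.jxy, self.jxx - self.jyy) + np.pi / 2, np.pi
        )
        self.ai_map = anisotropy_index(self.lam1, self.lam2)


def gaussian_derivative_kernels(size: int, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled x- and y-derivative-of-Gaussian kernels of odd ``size``.

    Returns (kx, ky) with array axis 0 = rows (y) and axis 1 = columns (x);
    kx responds to intensity change along x (columns).
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("kernel size must be odd and >= 3")
    half = size // 2
    u = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(u**2) / (2 * sigma**2))
    g /= g.sum()
    dg = -(u / sigma**2) * np.exp(-(u**2) / (2 * sigma**2))
    # normalize so the filter reproduces unit slope on a linear ramp
    dg /= np.sum(-u * dg)
    kx = np.outer(g, dg)
    ky = np.outer(dg, g)
    return kx, ky


def gaussian_derivatives(
    img: HistoImage | np.ndarray, cfg: STConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Directional image derivatives by Gaussian-derivative convolution.

    Boundary handling is by reflection. Returns (Ix, Iy) where Ix is the
    derivative along columns (x) and Iy along rows (y).
    """
    cfg = cfg or STConfig()
    gray = img.gray if isinstance(img, HistoImage) else to_grayscale(img)
    if min(gray.shape) < cfg.deriv_kernel_size:
        raise ValueError(
            f"image {gray.shape} smaller than derivative kernel "
            f"({cfg.deriv_kernel_size} px)"
        )
    kx, ky = gaussian_derivative_kernels(cfg.deriv_kernel_size, cfg.deriv_sigma)
    # correlate with flipped kernel == true convolution
    ix = ndimage.convolve(gray, kx, mode="reflect")
    iy = ndimage.convolve(gray, ky, mode="reflect")
    return ix, iy


def _tile_sum(a: np.ndarray, w: int) -> np.ndarray:
    """Sum over non-overlapping w x w tiles; partial border tiles dropped."""
    nr, nc = a.shape[0] // w, a.shape[1] // w
    if nr == 0 or nc == 0:
        raise ValueError(f"image {a.shape} smaller than one {w}x{w} window")
    trimmed = a[: nr * w, : nc * w]
    return trimmed.reshape(nr, w, nc, w).sum(axis=(1, 3))


def structure_tensor_field(
    ix: np.ndarray, iy: np.ndarray, cfg: STConfig | None = None
) -> STField:
    """Aggregate pixelwise gradient outer products into an ``STField``.

    The pixelwise tensor is [[Ix^2, IxIy], [IxIy, Iy^2]]. In ``tiled`` mode
    one tensor is produced per non-overlapping window; in ``sliding`` mode a
    per-pixel box sum over the window is used.
    """
    cfg = cfg or STConfig()
    ix = np.asarray(ix, dtype=float)
    iy = np.asarray(iy, dtype=float)
    if ix.shape != iy.shape:
        raise ValueError("Ix and Iy must have identical shapes")
    jxx, jxy, jyy = ix * ix, ix * iy, iy * iy
    if cfg.aggregation == "tiled":
        agg = lambda a: _tile_sum(a, cfg.window)  # noqa: E731
    else:
        agg = lambda a: ndimage.uniform_filter(  # noqa: E731
            a, size=cfg.window, mode="constant"
        ) * (cfg.window**2)
    return STField(
        jxx=agg(jxx), jxy=agg(jxy), jyy=agg(jyy),
        aggregation=cfg.aggregation, window=cfg.window,
    )


def anisotropy_index(lam1: np.ndarray | float, lam2: np.ndarray | float) -> np.ndarray | float:
    """AI = (lam1 - lam2)/(lam1 + lam2); defined 0 where both eigenvalues vanish."""
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam2 < -1e-12 * np.maximum(lam1, 1.0)) or np.any(lam1 < lam2 - 1e-12):
        raise ValueError("eigenvalues must satisfy lam1 >= lam2 >= 0")
    total = lam1 + lam2
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(total > 0, (lam1 - lam2) / np.where(total > 0, total, 1.0), 0.0)
    return ai if ai.ndim else float(ai)


def roi_ai(field: STField, mask: np.ndarray) -> dict[str, float]:
    """Summarise AI over an ROI mask.

    The mask is given on the field's own grid (tile grid in tiled mode). Two
    summaries are returned: ``ai_tensor`` — the AI of the tensor obtained by
    summing the tensors of all covered locations (the physically aggregated
    anisotropy), and ``ai_mean`` — the mean of the per-location AI values.
    They differ when covered locations have conflicting orientations.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.ai_map.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match field grid {field.ai_map.shape}"
        )
    if not mask.any():
        raise ValueError("empty ROI mask")
    jxx = float(field.jxx[mask].sum())
    jxy = float(field.jxy[mask].sum())
    jyy = float(field.jyy[mask].sum())
    half_diff = 0.5 * (jxx - jyy)
    disc = float(np.sqrt(half_diff**2 + jxy**2))
    lam1 = 0.5 * (jxx + jyy) + disc
    lam2 = max(0.5 * (jxx + jyy) - disc, 0.0)
    return {
        "ai_tensor": float(anisotropy_index(lam1, lam2)),
        "ai_mean": float(field.ai_map[mask].mean()),
        "n_locations": int(mask.sum()),
    }


def image_mask_to_tile_mask(mask: np.ndarray, window: int, min_fraction: float = 0.0) -> np.ndarray:
    """Convert a pixel-resolution ROI mask to the tile grid.

    A tile is covered when the fraction of its pixels inside the mask exceeds
    ``min_fraction`` (default: any overlap).
    """
    frac = _tile_sum(np.asarray(mask, dtype=float), window) / float(window**2)
    return frac > min_fraction


def analyze_image(
    img: HistoImage | np.ndarray,
    cfg: STConfig | None = None,
    roi_mask: np.ndarray | None = None,
) -> tuple[STField, dict[str, float] | None]:
    """Full ST pass: derivatives, tensor aggregation and optional ROI summary.

    ``roi_mask`` is given at image resolution; in tiled mode it is reduced to
    the tile grid by any-overlap coverage.
    """
    cfg = cfg or STConfig()
    ix, iy = gaussian_derivatives(img, cfg)
    field = structure_tensor_field(ix, iy, cfg)
    summary = None
    if roi_mask is not None:
        mask = np.asarray(roi_mask, dtype=bool)
        if cfg.aggregation == "tiled":
            mask = image_mask_to_tile_mask(mask, cfg.window)
        summary = roi_ai(field, mask)
    return field, summary
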