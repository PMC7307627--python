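"""Synthetic fixtures: fiber textures, Nissl-like cell images, DWI signals
and sham/mTBI ROI cohorts.

Every generator is deterministic given (spec, seed) and emits its ground
truth in machine-readable form alongside the data, so the analysis modules
can be validated end-to-end without any deposited imaging data.

* ``gen_fiber_image`` mixes a perfectly oriented band-limited texture with an
  isotropic one; the ``coherence`` parameter is the fraction of texture
  amplitude that is aligned, so structure-tensor anisotropy should grow
  monotonically with it.
* ``gen_nissl_image`` renders dark elliptical somata (blue-violet on a light
  background, strongest contrast in the green channel) with known count and
  centroids; a configurable fraction of cells is placed as touching pairs
  whose fused component exceeds the under-segmentation bound.
* ``gen_dwi`` simulates the mono-exponential tensor signal
  S = S0 exp(-b g^T D g) under a given protocol, optionally with noise.
* ``gen_cohort`` draws per-animal ROI records from group/region means and
  SDs; the default parameterization encodes a 14-animal two-group study
  (sham n=6, mTBI n=8) whose only real effects sit in the ipsilateral
  hemisphere at the lesion level (-3.60 mm from bregma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dti_metrics import DWIProtocol, TensorEigenvalues
from .roi_stats import GROUPS, HEMISPHERES, LEVELS, REGIONS_BY_LEVEL
from .st_analysis import HistoImage

__all__ = [
    "FiberImageSpec",
    "NisslImageSpec",
    "CohortSpec",
    "gen_fiber_image",
    "gen_nissl_image",
    "gen_dwi",
    "gen_cohort",
    "DEFAULT_COHORT_PARAMS",
]


# ---------------------------------------------------------------------------
# fiber texture


@dataclass
class FiberImageSpec:
    """Oriented-texture image spec.

    orientation: fiber direction in radians, measured from the column (x)
    axis; coherence in [0, 1] is the aligned fraction of texture amplitude;
    fiber_width (pixels) sets the texture correlation length.
    """

    size: int = 512
    orientation: float = 0.0
    coherence: float = 1.0
    fiber_width: float = 4.0
    noise_sd: float = 0.01
    amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coherence <= 1:
            raise ValueError("coherence must lie in [0, 1]")
        if self.size < 256:
            raise ValueError("size must be >= 256 for windowed ST analysis")


def _unit_std(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return a / sd if sd > 0 else a


def gen_fiber_image(spec: FiberImageSpec) -> tuple[HistoImage, float]:
    """Generate a fibrous texture; returns (image, true orientation).

    The coherent component is constant along the fiber direction and a
    smoothed random profile across it; the isotropic component is smoothed
    2D noise. Both are normalised to unit variance before mixing with
    weights (coherence, 1 - coherence).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    # across-fiber coordinate (perpendicular to the fiber direction)
    u = -np.sin(spec.orientation) * cols + np.cos(spec.orientation) * rows
    # smooth 1D random profile, sampled at u
    m = int(np.ceil(2 * np.sqrt(2) * n)) + 8
    profile = ndimage.gaussian_filter1d(
        rng.standard_normal(m), spec.fiber_width, mode="wrap"
    )
    grid = np.arange(m) - m / 2
    aniso = _unit_std(np.interp(u.ravel(), grid, profile).reshape(u.shape))
    iso = _unit_std(ndimage.gaussian_filter(
        rng.standard_normal((n, n)), spec.fiber_width, mode="wrap"))
    texture = spec.coherence * aniso + (1 - spec.coherence) * iso
    img = 0.5 + spec.amplitude * texture + spec.noise_sd * rng.standard_normal((n, n))
    img = np.clip(img, 0.0, 1.0)
    return HistoImage(pixels=img, stain="myelin"), spec.orientation % np.pi


# ---------------------------------------------------------------------------
# Nissl-like cell images


@dataclass
class NisslImageSpec:
    """Cell-image spec with planted ground truth.

    Single-cell ellipse major axes default to 45-90 px, inside the
    30-140 px acceptance band of the counting pipeline; touching pairs use
    85-100 px cells whose fused component exceeds the 140 px bound while
    their centers stay farther apart than the 70 px marker-separation rule.
    """

    size: int = 768
    n_cells: int = 30
    major_range: tuple[float, float] = (45.0, 90.0)
    pair_major_range: tuple[float, float] = (85.0, 100.0)
    minor_ratio_range: tuple[float, float] = (0.55, 0.85)
    fraction_touching: float = 0.1
    contrast_range: tuple[float, float] = (0.5, 0.7)
    noise_sd: float = 0.005
    blur_sigma: float = 1.0
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 <= self.fraction_touching <= 1:
            raise ValueError("fraction_touching must lie in [0, 1]")
        if self.major_range[0] <= 0:
            raise ValueError("axis ranges must be positive")


#: light background and per-channel absorption of the violet stain; the
#: green channel absorbs most, giving it the sharpest membrane contrast
_NISSL_BG = np.array([0.88, 0.90, 0.94])
_NISSL_DROP = np.array([0.70, 1.00, 0.55])


def _cell_profile(shape, center, major, minor, angle, depth, grid):
    rows, cols = grid
    dr, dc = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    # coordinates along (u) / across (v) the major axis; angle from col axis
    uu = dc * ca + dr * sa
    vv = -dc * sa + dr * ca
    r2 = (uu / (major / 2)) ** 2 + (vv / (minor / 2)) ** 2
    return depth * np.clip(1.0 - r2, 0.0, None)


def gen_nissl_image(spec: NisslImageSpec) -> tuple[HistoImage, dict]:
    """Render a Nissl-like RGB image and its ground truth.

    Returns (image, truth) where truth holds the planted cell count,
    centroids (row, col), ellipse axes and the index pairs of touching
    cells. Cell interiors darken toward the centroid so each soma keeps a
    distinct intensity maximum even inside a fused pair.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    grid = np.mgrid[0:n, 0:n].astype(float)
    n_pair_cells = 2 * int(round(spec.fraction_touching * spec.n_cells / 2))
    n_pairs = n_pair_cells // 2
    n_single = spec.n_cells - n_pair_cells

    placed: list[dict] = []  # center, major, minor, angle, depth
    pair_indices: list[tuple[int, int]] = []

    def far_enough(center, extent) -> bool:
        for cell in placed:
            d = np.hypot(center[0] - cell["center"][0], center[1] - cell["center"][1])
            if d < extent / 2 + cell["major"] / 2 + 20:
                return False
        return True

    def rand_depth(avoid: float | None = None) -> float:
        lo, hi = spec.contrast_range
        for _ in range(100):
            c = rng.uniform(lo, hi)
            if avoid is None or abs(c - avoid) >= 0.03:
                return c
        return hi if avoid is not None and avoid < (lo + hi) / 2 else lo

    tries = 0
    for _ in range(n_pairs):
        while True:
            tries += 1
            if tries > spec.max_place_tries:
                raise RuntimeError("could not place all cells; reduce n_cells or size")
            major = rng.uniform(*spec.pair_major_range)
            dist = max(78.0, 0.9 * major)
            axis_angle = rng.uniform(0, np.pi)
            extent = major + dist
            margin = extent / 2 + 10
            center = rng.uniform(margin, n - margin, size=2)
            if not far_enough(center, extent):
                continue
            offset = 0.5 * dist * np.array([np.sin(axis_angle), np.cos(axis_angle)])
            d1 = rand_depth()
            d2 = rand_depth(avoid=d1)
            i0 = len(placed)
            for c, d in ((center - offset, d1), (center + offset, d2)):
                placed.append({
                    "center": tuple(c), "major": major,
                    "minor": major * rng.uniform(*spec.minor_ratio_range),
                    "angle": axis_angle, "depth": d,
                })
            pair_indices.append((i0, i0 + 1))
            break

    for _ in range(n_single):
        while True:
            tries += 1
            if tries > spec.max_place_tries:
                raise RuntimeError("could not place all cells; reduce n_cells or size")
            major = rng.uniform(*spec.major_range)
            margin = major / 2 + 10
            center = rng.uniform(margin, n - margin, size=2)
            if not far_enough(center, major):
                continue
            placed.append({
                "center": tuple(center), "major": major,
                "minor": major * rng.uniform(*spec.minor_ratio_range),
                "angle": rng.uniform(0, np.pi), "depth": rand_depth(),
            })
            break

    absorb = np.zeros((n, n))
    for cell in placed:
        profile = _cell_profile((n, n), cell["center"], cell["major"],
                                cell["minor"], cell["angle"], cell["depth"], grid)
        absorb = np.maximum(absorb, profile)
    rgb = _NISSL_BG[None, None, :] - absorb[..., None] * _NISSL_DROP[None, None, :]
    if spec.blur_sigma > 0:
        rgb = ndimage.gaussian_filter(rgb, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    rgb = np.clip(rgb + spec.noise_sd * rng.standard_normal(rgb.shape), 0.0, 1.0)
    truth = {
        "n_cells": len(placed),
        "centroids": [list(map(float, c["center"])) for c in placed],
        "major_axes": [float(c["major"]) for c in placed],
        "minor_axes": [float(c["minor"]) for c in placed],
        "pairs": [list(p) for p in pair_indices],
        "seed": spec.seed,
    }
    return HistoImage(pixels=rgb, stain="nissl"), truth


# ---------------------------------------------------------------------------
# diffusion-weighted signals


def gen_dwi(
    ev: TensorEigenvalues | np.ndarray,
    protocol: DWIProtocol,
    rotation: np.ndarray | None = None,
    s0: float = 1.0,
    snr: float | None = None,
    seed: int = 0,
    rician: bool = False,
) -> np.ndarray:
    """Simulate DWI signals S = S0 exp(-b g^T D g) for one tensor.

    ``rotation`` (3x3 orthogonal) orients the tensor's eigenframe. With
    ``snr`` set, Gaussian noise of SD S0/snr is added (Rician magnitude
    noise via ``rician=True``).
    """
    lam = ev.as_array() if isinstance(ev, TensorEigenvalues) else np.asarray(ev, dtype=float)
    d = np.diag(lam)
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        d = rotation @ d @ rotation.T
    g = protocol.bvecs
    quad = np.einsum("ni,ij,nj->n", g, d, g)
    s = s0 * np.exp(-protocol.bvals * quad)
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        if rician:
            s = np.sqrt((s + sigma * rng.standard_normal(s.shape)) ** 2
                        + (sigma * rng.standard_normal(s.shape)) ** 2)
        else:
            s = s + sigma * rng.standard_normal(s.shape)
    return s


# ---------------------------------------------------------------------------
# ROI cohorts


def _default_cohort_params() -> dict:
    """Group means and SDs per (group, hemisphere, level, region).

    AI and CD (x1e-2 cells/um^2) encode a two-group study whose real
    effects are confined to the ipsilateral hemisphere of the lesion level
    (-3.60 mm): lowered anisotropy in the external capsule and raised cell
    density in the external capsule, somatosensory cortex and internal
    capsule. FA and AD (x1e-3 mm^2/s) are derived from the AI level of each
    cell (FA = 0.85*AI, AD = 0.9 + 0.5*AI) so that DTI and histology
    co-vary across regions the way white/gray matter contrast makes them.
    """
    ai_cd = {
        # level: {region: {hemi: {group: ((ai_mean, ai_sd), (cd_mean, cd_sd))}}}
        1.08: {
            "cc": {"ipsilateral": {"sham": ((0.81, 0.05), (0.53, 0.03)),
                                   "mTBI": ((0.83, 0.03), (0.52, 0.04))},
                   "contralateral": {"sham": ((0.80, 0.04), (0.52, 0.04)),
                                     "mTBI": ((0.81, 0.03), (0.52, 0.02))}},
            "ec": {"ipsilateral": {"sham": ((0.73, 0.04), (0.43, 0.03)),
                                   "mTBI": ((0.71, 0.04), (0.44, 0.04))},
                   "contralateral": {"sham": ((0.75, 0.03), (0.44, 0.05)),
                                     "mTBI": ((0.75, 0.03), (0.46, 0.05))}},
            "S1": {"ipsilateral": {"sham": ((0.43, 0.06), (0.39, 0.02)),
                                   "mTBI": ((0.47, 0.06), (0.40, 0.06))},
                   "contralateral": {"sham": ((0.47, 0.04), (0.39, 0.01)),
                                     "mTBI": ((0.47, 0.01), (0.38, 0.03))}},
        },
        -1.60: {
            "cc": {"ipsilateral": {"sham": ((0.85, 0.02), (0.51, 0.05)),
                                   "mTBI": ((0.82, 0.04), (0.55, 0.04))},
                   "contralateral": {"sham": ((0.84, 0.04), (0.50, 0.02)),
                                     "mTBI": ((0.82, 0.03), (0.53, 0.03))}},
            "ec": {"ipsilateral": {"sham": ((0.71, 0.06), (0.43, 0.04)),
                                   "mTBI": ((0.66, 0.03), (0.50, 0.05))},
                   "contralateral": {"sham": ((0.73, 0.02), (0.42, 0.03)),
                                     "mTBI": ((0.72, 0.05), (0.44, 0.04))}},
            "S1": {"ipsilateral": {"sham": ((0.38, 0.05), (0.39, 0.02)),
                                   "mTBI": ((0.38, 0.06), (0.41, 0.03))},
                   "contralateral": {"sham": ((0.45, 0.05), (0.39, 0.02)),
                                     "mTBI": ((0.44, 0.05), (0.39, 0.02))}},
        },
        -3.60: {
            "cc": {"ipsilateral": {"sham": ((0.83, 0.04), (0.50, 0.06)),
                                   "mTBI": ((0.78, 0.05), (0.52, 0.06))},
                   "contralateral": {"sham": ((0.80, 0.06), (0.49, 0.03)),
                                     "mTBI": ((0.75, 0.07), (0.50, 0.06))}},
            "ec": {"ipsilateral": {"sham": ((0.76, 0.03), (0.44, 0.03)),
                                   "mTBI": ((0.60, 0.08), (0.56, 0.06))},
                   "contralateral": {"sham": ((0.73, 0.04), (0.43, 0.03)),
                                     "mTBI": ((0.78, 0.03), (0.42, 0.03))}},
            "S1": {"ipsilateral": {"sham": ((0.34, 0.07), (0.39, 0.02)),
                                   "mTBI": ((0.30, 0.05), (0.46, 0.05))},
                   "contralateral": {"sham": ((0.35, 0.09), (0.39, 0.03)),
                                     "mTBI": ((0.33, 0.04), (0.38, 0.01))}},
            "ic": {"ipsilateral": {"sham": ((0.53, 0.09), (0.38, 0.03)),
                                   "mTBI": ((0.47, 0.04), (0.45, 0.02))},
                   "contralateral": {"sham": ((0.56, 0.08), (0.38, 0.02)),
                                     "mTBI": ((0.57, 0.04), (0.35, 0.04))}},
            "VPL": {"ipsilateral": {"sham": ((0.43, 0.03), (0.33, 0.03)),
                                    "mTBI": ((0.43, 0.03), (0.38, 0.04))},
                    "contralateral": {"sham": ((0.45, 0.05), (0.33, 0.03)),
                                      "mTBI": ((0.44, 0.04), (0.34, 0.03))}},
        },
    }
    params: dict = {}
    for level, regions in ai_cd.items():
        for region, hemis in regions.items():
            for hemi, groups in hemis.items():
                for group, ((ai_m, ai_s), (cd_m, cd_s)) in groups.items():
                    params[(group, hemi, level, region)] = {
                        "AI": (ai_m, ai_s),
                        "CD": (cd_m, cd_s),
                        "FA": (0.85 * ai_m, 0.05),
                        "AD": (0.9 + 0.5 * ai_m, 0.08),
                    }
    return params


DEFAULT_COHORT_PARAMS = _default_cohort_params()


@dataclass
class CohortSpec:
    """Cohort generator spec: per-cell means/SDs and group sizes.

    ``params`` maps (group, hemisphere, level, region) to
    {measure: (mean, sd)} for AI, CD, FA and AD. Default group sizes are
    sham = 6 and mTBI = 8 animals.
    """

    params: dict = field(default_factory=_default_cohort_params)
    n_sham: int = 6
    n_mtbi: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sham < 2 or self.n_mtbi < 2:
            raise ValueError("group sizes must be >= 2")
        for key, measures in self.params.items():
            for measure, (_m, sd) in measures.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {key}/{measure}")


def gen_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a tidy ROI table: one row per (animal, hemisphere, level, region).

    Measures are independent Gaussian draws from the cell's (mean, sd);
    there is no within-animal correlation across regions.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    animals = ([("sham", f"s{i + 1}") for i in range(spec.n_sham)]
               + [("mTBI", f"m{i + 1}") for i in range(spec.n_mtbi)])
    rows = []
    for group, animal in animals:
        for hemi in HEMISPHERES:
            for level in LEVELS:
                for region in REGIONS_BY_LEVEL[level]:
                    cell = spec.params.get((group, hemi, level, region))
                    if cell is None:
                        continue
                    row = {"animal_id": animal, "group": group,
                           "hemisphere": hemi, "level": level, "region": region}
                    for measure in ("AI", "CD", "FA", "AD"):
                        mean, sd = cell[measure]
                        row[measure] = rng.normal(mean, sd)
                    rows.append(row)
    return pd.DataFrame(rows)
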