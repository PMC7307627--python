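"""Diffusion-tensor scalar metrics and a log-linear tensor fit.

From the sorted eigenvalues (l1 >= l2 >= l3, mm^2/s) of a diffusion tensor:

    MD = (l1 + l2 + l3) / 3          mean diffusivity
    AD = l1                          axial diffusivity
    RD = (l2 + l3) / 2               radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||

plus the Westin shape indices in the l1-normalised convention

    CL = (l1 - l2)/l1,  CP = (l2 - l3)/l1,  CS = l3/l1,   CL + CP + CS = 1,

which partition anisotropy into linear, planar and spherical components.
A sum-normalised variant (denominator l1+l2+l3, indices CL=(l1-l2)/sum etc.)
is available via ``westin="sum"``.

``fit_tensor`` recovers a tensor from diffusion-weighted signals by ordinary
least squares on log(S): with b-value b and unit gradient g,
S = S0 * exp(-b g^T D g), so log S is linear in the six unique tensor
elements and log S0. The fit is exact for noiseless signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TensorEigenvalues",
    "DTIScalars",
    "DWIProtocol",
    "scalars_from_eigenvalues",
    "fit_tensor",
    "roi_scalar_summary",
]


@dataclass
class TensorEigenvalues:
    """Sorted diffusion eigenvalues (mm^2/s), l1 >= l2 >= l3.

    Negative values can arise from noisy fits; they are accepted only when
    ``from_fit`` is set, and downstream scalars are computed on the raw
    values (no clamping).
    """

    l1: float
    l2: float
    l3: float
    from_fit: bool = False

    def __post_init__(self) -> None:
        vals = (self.l1, self.l2, self.l3)
        if not all(np.isfinite(vals)):
            raise ValueError("eigenvalues must be finite")
        if not (self.l1 >= self.l2 >= self.l3):
            raise ValueError("eigenvalues must be sorted l1 >= l2 >= l3")
        if self.l3 < 0 and not self.from_fit:
            raise ValueError("negative eigenvalues allowed only for fit results")

    def as_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3], dtype=float)


@dataclass
class DTIScalars:
    fa: float
    md: float
    ad: float
    rd: float
    cl: float
    cp: float
    cs: float


@dataclass
class DWIProtocol:
    """Acquisition geometry: b-values (s/mm^2) and unit gradient directions.

    delta/Delta (ms) are carried as metadata only. A tensor fit needs at
    least six non-collinear diffusion-weighted directions plus one b=0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3), unit norm for b > 0
    delta: float | None = None
    Delta: float | None = None

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] == 3:
            self.bvecs = self.bvecs.T  # accept FSL 3xN layout
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must be (N, 3) matching bvals")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("diffusion-weighted gradient directions must be unit norm")

    @classmethod
    def standard(cls, n_dirs: int = 60, bval: float = 2000.0, n_b0: int = 4,
                 seed: int = 0) -> "DWIProtocol":
        """Default protocol: ``n_b0`` b=0 volumes + ``n_dirs`` directions at
        ``bval`` s/mm^2, spread quasi-uniformly on the sphere (Fibonacci
        lattice, deterministically rotated by ``seed``)."""
        i = np.arange(n_dirs, dtype=float)
        golden = (1 + 5**0.5) / 2
        z = 1 - (2 * i + 1) / n_dirs
        theta = 2 * np.pi * i / golden
        r = np.sqrt(np.maximum(1 - z**2, 0.0))
        dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        if seed:
            rng = np.random.default_rng(seed)
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            dirs = dirs @ q.T
        bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
        bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
        return cls(bvals=bvals, bvecs=bvecs, delta=4.0, Delta=11.0)


def scalars_from_eigenvalues(
    ev: TensorEigenvalues | np.ndarray, westin: str = "lambda1"
) -> DTIScalars:
    """Compute FA/MD/AD/RD and Westin CL/CP/CS from sorted eigenvalues.

    For the degenerate all-zero tensor, FA = CL = CP = 0 and CS = 1 by
    convention (a warning is emitted).
    """
    lam = ev.as_array() if isinstance(ev, TensorEigenvalues) else np.asarray(ev, dtype=float)
    if lam.shape != (3,):
        raise ValueError("expected three eigenvalues")
    if not (lam[0] >= lam[1] >= lam[2]):
        raise ValueError("eigenvalues must be sorted descending")
    l1, l2, l3 = lam
    md = lam.mean()
    ad = l1
    rd = 0.5 * (l2 + l3)
    norm_sq = float(lam @ lam)
    if norm_sq == 0.0:
        warnings.warn("all-zero tensor: FA/CL/CP set to 0, CS to 1", stacklevel=2)
        return DTIScalars(fa=0.0, md=0.0, ad=0.0, rd=0.0, cl=0.0, cp=0.0, cs=1.0)
    fa = float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / norm_sq))
    if westin == "lambda1":
        denom = l1
    elif westin == "sum":
        denom = l1 + l2 + l3
    else:
        raise ValueError("westin must be 'lambda1' or 'sum'")
    if denom == 0.0:
        cl = cp = 0.0
        cs = 1.0
    elif westin == "lambda1":
        cl, cp, cs = (l1 - l2) / denom, (l2 - l3) / denom, l3 / denom
    else:
        cl, cp, cs = (l1 - l2) / denom, 2 * (l2 - l3) / denom, 3 * l3 / denom
    return DTIScalars(fa=fa, md=float(md), ad=float(ad), rd=float(rd),
                      cl=float(cl), cp=float(cp), cs=float(cs))


def _design_matrix(protocol: DWIProtocol) -> np.ndarray:
    b = protocol.bvals
    g = protocol.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    # columns: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0
    return np.column_stack([
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
        np.ones_like(b),
    ])


def fit_tensor(
    signals: np.ndarray, protocol: DWIProtocol
) -> tuple[TensorEigenvalues, np.ndarray, float]:
    """Log-linear least-squares diffusion tensor fit.

    Returns (eigenvalues sorted descending, eigenvectors as columns matching
    that order, S0). Non-positive signals are excluded with a warning;
    negative eigenvalues are kept and flagged via ``from_fit``.
    """
    s = np.asarray(signals, dtype=float).ravel()
    if len(s) != len(protocol.bvals):
        raise ValueError("signal count does not match protocol")
    keep = s > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} non-positive signals", stacklevel=2)
    x = _design_matrix(protocol)[keep]
    if len(s[keep]) < 7:
        raise ValueError("need >= 7 positive measurements including b=0")
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("rank-deficient design: directions do not span tensor space")
    coef, *_ = np.linalg.lstsq(x, np.log(s[keep]), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz, log_s0 = coef
    d = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    w, v = np.linalg.eigh(d)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    ev = TensorEigenvalues(l1=float(w[0]), l2=float(w[1]), l3=float(w[2]), from_fit=True)
    return ev, v, float(np.exp(log_s0))


def roi_scalar_summary(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean of a scalar map over an ROI; NaN voxels are excluded and counted."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share one grid")
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = volume[mask]
    n_nan = int(np.isnan(vals).sum())
    valid = vals[~np.isnan(vals)]
    if valid.size == 0:
        raise ValueError("ROI contains only NaN voxels")
    return {"mean": float(valid.mean()), "n_voxels": int(valid.size), "n_nan": n_nan}
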