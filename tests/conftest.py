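import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def brute_force_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2D convolution by direct summation with reflect padding.

    Independent oracle for the package's filtered derivatives: pads with
    edge-mirrored values, flips the kernel, and accumulates term by term.
    """
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="symmetric")
    flipped = kernel[::-1, ::-1]
    out = np.zeros_like(image, dtype=float)
    for di in range(kh):
        for dj in range(kw):
            out += flipped[di, dj] * padded[di:di + image.shape[0],
                                            dj:dj + image.shape[1]]
    return out


def brute_force_tile_tensors(ix: np.ndarray, iy: np.ndarray, w: int):
    """Per-tile structure-tensor sums by explicit python loops."""
    nr, nc = ix.shape[0] // w, ix.shape[1] // w
    jxx = np.zeros((nr, nc))
    jxy = np.zeros((nr, nc))
    jyy = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            for i in range(r * w, (r + 1) * w):
                for j in range(c * w, (c + 1) * w):
                    jxx[r, c] += ix[i, j] * ix[i, j]
                    jxy[r, c] += ix[i, j] * iy[i, j]
                    jyy[r, c] += iy[i, j] * iy[i, j]
    return jxx, jxy, jyy


def bh_stepup_reference(pvals):
    """Benjamini--Hochberg adjusted p-values straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
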