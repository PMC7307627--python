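"""Diffusion-tensor scalar metrics and the log-linear tensor fit.

Evaluates FA/MD/AD/RD and the Westin shape indices for a prolate
white-matter-like tensor, then simulates diffusion-weighted signals under a
60-direction b = 2000 s/mm^2 protocol, refits the tensor, and shows that
noiseless signals invert exactly.
"""

import numpy as np

from histotensor import (DWIProtocol, fit_tensor, gen_dwi,
                         scalars_from_eigenvalues)

evals = np.array([1.7, 0.3, 0.3]) * 1e-3  # mm^2/s
sc = scalars_from_eigenvalues(evals)
print("eigenvalues (x1e-3 mm^2/s):", evals * 1e3)
print(f"  FA = {sc.fa:.4f}   MD = {sc.md * 1e3:.4f}e-3   "
      f"AD = {sc.ad * 1e3:.1f}e-3   RD = {sc.rd * 1e3:.1f}e-3")
print(f"  Westin CL = {sc.cl:.4f}  CP = {sc.cp:.4f}  CS = {sc.cs:.4f}  "
      f"(sum = {sc.cl + sc.cp + sc.cs:.1f})")

protocol = DWIProtocol.standard(n_dirs=60, bval=2000.0)
signals = gen_dwi(evals, protocol, s0=1000.0)
fit, _, s0 = fit_tensor(signals, protocol)
print(f"\nnoiseless fit from {len(signals)} signals: "
      f"eigenvalues {fit.as_array() * 1e3} x1e-3, S0 = {s0:.1f}")
print(f"max eigenvalue error: {np.abs(fit.as_array() - evals).max():.2e} mm^2/s")

noisy = gen_dwi(evals, protocol, s0=1000.0, snr=100, seed=4)
fit_n, _, _ = fit_tensor(np.clip(noisy, 1e-3, None), protocol)
sc_n = scalars_from_eigenvalues(fit_n.as_array())
print(f"with SNR 100 noise: FA = {sc_n.fa:.4f} (true {sc.fa:.4f})")
print("\nThe log-linear fit is exact on noiseless data. At b = 2000 s/mm^2 "
      "the strongly attenuated signals sit close to the noise floor even at "
      "high SNR, so noise biases FA upward -- a known property of "
      "log-linear tensor estimation.")
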