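"""Spatially contiguous heterogeneity field applied to binary activity masks.

A random periodic field is synthesized as a truncated 3D Fourier series

    F(x, y, z) = sum_{k,j,l = -M..M}  g_kjl * cos(2*pi*(k*x + j*y + l*z)/p
                                                 + phi_kjl)
                                      / (k^2 + j^2 + l^2)^beta

with Gaussian amplitudes g (mean 0, SD 1), phases phi uniform in
(-pi, pi], period ``p`` in voxels, cutoff ``M`` and spectral exponent
``beta``.  The (0,0,0) term divides by zero and is excluded; it would
only add a constant offset, which the min-max rescale removes anyway.

Multiplying the field into a binary mask and rescaling the active voxels
to integers in [floor, 100] yields a heterogeneous relative activity
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeterogeneityField", "evaluate_field", "apply_heterogeneity"]


@dataclass
class HeterogeneityField:
    """Frozen draw of the Fourier coefficients.

    ``g`` and ``phi`` are arrays of shape (2M+1, 2M+1, 2M+1) indexed by
    (k, j, l) offset by +M; the (0,0,0) entry is present but never used.
    """

    beta: float
    M: int
    p: int
    g: np.ndarray
    phi: np.ndarray
    seed: int

    @classmethod
    def draw(cls, seed: int, beta: float = 0.9, M: int = 8, p: int = 50
             ) -> "HeterogeneityField":
        rng = np.random.default_rng(seed)
        size = 2 * M + 1
        g = rng.standard_normal((size, size, size))
        # uniform on (-pi, pi]
        phi = -(rng.random((size, size, size)) * 2.0 - 1.0) * np.pi
        return cls(beta=beta, M=M, p=p, g=g, phi=phi, seed=seed)


def evaluate_field(fld: HeterogeneityField, shape: tuple[int, int, int]
                   ) -> np.ndarray:
    """Evaluate the Fourier series at every integer voxel of ``shape``.

    Because (x, y, z) are integer voxel indices, the series only depends
    on the indices modulo p.  Each cosine term is the real part of
    ``g * exp(i*phi) * exp(2*pi*i*(kx+jy+lz)/p)``, so the whole field on
    one p**3 period is a single inverse DFT of the complex coefficient
    array; the voxel grid then samples that period by index wrapping.
    """
    M, p = fld.M, fld.p
    coeff = np.zeros((p, p, p), dtype=complex)
    ks = np.arange(-M, M + 1)
    c = fld.g * np.exp(1j * fld.phi)
    c[M, M, M] = 0.0  # excluded (0,0,0) term
    k2 = ks[:, None, None] ** 2 + ks[None, :, None] ** 2 + ks[None, None, :] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = np.where(k2 > 0, c / np.where(k2 > 0, k2, 1) ** fld.beta, 0.0)
    idx = np.mod(ks, p)
    # frequencies beyond the p-grid alias exactly for integer coordinates
    np.add.at(coeff, np.ix_(idx, idx, idx), amp)
    period = np.real(np.fft.ifftn(coeff)) * p**3
    xi, yi, zi = (np.arange(s) % p for s in shape)
    return period[np.ix_(xi, yi, zi)]


def apply_heterogeneity(mask: np.ndarray, values: np.ndarray,
                        floor: int = 1) -> np.ndarray:
    """Modulate a binary mask by a field and rescale to integers.

    Active voxels are mapped affinely so that the smallest field value
    over the mask becomes ``floor`` and the largest becomes 100, then
    rounded; inactive voxels stay 0.  A constant field over the active
    voxels maps every active voxel to 100.
    """
    if mask.shape != values.shape:
        raise ValueError("mask and field must share a grid")
    active = mask > 0
    out = np.zeros(mask.shape, dtype=np.int16)
    if not active.any():
        warnings.warn("all-zero activity mask; returned unchanged")
        return out
    v = values[active]
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12 * max(abs(hi), 1.0):
        out[active] = 100
        return out
    scaled = floor + (v - lo) * (100.0 - floor) / (hi - lo)
    out[active] = np.rint(scaled).astype(np.int16)
    return out
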