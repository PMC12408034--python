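"""Nonuniform Fourier evaluation by Kaiser-Bessel convolution gridding.

Implements the two operators the simulator needs on a 2D N x N image:

* ``forward``  (type 2): evaluate ``F(k) = sum_x f(x) exp(-2*pi*i k.x / N)``
  at arbitrary k-space locations (cycles/FOV, |k| <= N/2), with x the
  0-based pixel index measured from the image center ``N//2``.
* ``adjoint``  (type 1): the exact conjugate-transpose of ``forward``,
  mapping weighted samples back onto the N x N grid.

Both use a 2x-oversampled FFT grid and a width-6 Kaiser-Bessel
interpolation kernel with the Beatty shape parameter; deapodization uses
the numerically integrated continuous Fourier transform of the kernel, so
the operator pair matches a direct-summation DFT to ~1e-5 relative error.
"""
from __future__ import annotations

import math

import numpy as np

__all__ = ["GriddingNufft"]


class GriddingNufft:
    """Plan-style gridding operator for a fixed image size.

    Parameters
    ----------
    n : image matrix size (N x N)
    oversamp : FFT grid oversampling factor (integer multiple kept for
        exact center alignment; default 2)
    width : interpolation kernel full width in oversampled grid cells
    """

    def __init__(self, n: int, oversamp: int = 2, width: int = 6):
        self.n = int(n)
        self.os = int(oversamp)
        self.m = self.os * self.n
        self.width = int(width)
        w, s = float(width), float(oversamp)
        self.beta = math.pi * math.sqrt((w / s) ** 2 * (s - 0.5) ** 2 - 0.8)
        self._deapod = self._make_deapod()
        self._offsets = np.arange(-(self.width // 2 - 1), self.width // 2 + 1)

    def _kernel(self, u: np.ndarray) -> np.ndarray:
        z = 2.0 * np.asarray(u, dtype=float) / self.width
        out = np.zeros_like(z)
        inside = np.abs(z) < 1.0
        out[inside] = np.i0(self.beta * np.sqrt(1.0 - z[inside] ** 2))
        return out / np.i0(self.beta)

    def _make_deapod(self) -> np.ndarray:
        # continuous FT of the kernel, integrated numerically:
        #   c(p) = int kb(u) cos(2 pi u p / m) du,  p = centered pixel index
        u = np.linspace(-self.width / 2.0, self.width / 2.0, 4097)
        kb = self._kernel(u)
        p = np.arange(self.n) - self.n // 2
        phase = np.cos(2.0 * math.pi * np.outer(p, u) / self.m)
        c1 = np.trapezoid(phase * kb[None, :], u, axis=1)
        return np.outer(c1, c1)

    # -- forward ---------------------------------------------------------
    def plan_image(self, image: np.ndarray) -> np.ndarray:
        """Deapodize, zero-pad and FFT an image once; the returned spectrum
        can be interpolated at many coordinate sets via ``interpolate``."""
        if image.shape != (self.n, self.n):
            raise ValueError(f"image must be {self.n}x{self.n}")
        pad = np.zeros((self.m, self.m), dtype=complex)
        s = (self.m - self.n) // 2
        pad[s : s + self.n, s : s + self.n] = image / self._deapod
        return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pad)))

    def interpolate(self, spectrum: np.ndarray, coords: np.ndarray) -> np.ndarray:
        """Evaluate a planned spectrum at ``coords`` (..., 2) in cycles/FOV."""
        shape = coords.shape[:-1]
        kr = coords[..., 0].reshape(-1) * self.os
        kc = coords[..., 1].reshape(-1) * self.os
        fr = np.floor(kr).astype(np.int64)
        fc = np.floor(kc).astype(np.int64)
        half = self.m // 2
        out = np.zeros(kr.shape, dtype=complex)
        for dr in self._offsets:
            wr = self._kernel(kr - (fr + dr))
            ir = (fr + dr + half) % self.m
            for dc in self._offsets:
                wc = self._kernel(kc - (fc + dc))
                ic = (fc + dc + half) % self.m
                out += spectrum[ir, ic] * (wr * wc)
        return out.reshape(shape)

    def forward(self, image: np.ndarray, coords: np.ndarray) -> np.ndarray:
        """Type-2 NUFFT: nonuniform samples of the image's Fourier transform."""
        return self.interpolate(self.plan_image(image), coords)

    # -- adjoint ---------------------------------------------------------
    def adjoint(self, samples: np.ndarray, coords: np.ndarray) -> np.ndarray:
        """Type-1 (adjoint) NUFFT: grid samples back to an N x N image."""
        s = np.asarray(samples, dtype=complex).reshape(-1)
        kr = coords[..., 0].reshape(-1) * self.os
        kc = coords[..., 1].reshape(-1) * self.os
        if s.shape != kr.shape:
            raise ValueError("samples and coords disagree in length")
        fr = np.floor(kr).astype(np.int64)
        fc = np.floor(kc).astype(np.int64)
        half = self.m // 2
        grid = np.zeros(self.m * self.m, dtype=complex)
        for dr in self._offsets:
            wr = self._kernel(kr - (fr + dr))
            ir = (fr + dr + half) % self.m
            for dc in self._offsets:
                wc = self._kernel(kc - (fc + dc))
                ic = (fc + dc + half) % self.m
                np.add.at(grid, ir * self.m + ic, s * wr * wc)
        grid = grid.reshape(self.m, self.m)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid))) * (self.m * self.m)
        lo = (self.m - self.n) // 2
        img = img[lo : lo + self.n, lo : lo + self.n]
        return img / self._deapod
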