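"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they validate: the Bloch oracle is
an explicit-Euler time stepper (its per-interval geometric recurrence is
evaluated in closed form, which is bit-equivalent to running the Euler
steps one by one), and the Fourier oracles are direct O(M * N^2)
summations.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.special import j1


def euler_steady_mz(seq, tissue, dt_us: float = 1.0, max_tr: int = 500) -> np.ndarray:
    """Pre-pulse Mz per excitation slot from explicit-Euler integration of
    dMz/dt = (1 - Mz)/T1 with event handling, iterated to steady state."""
    t1 = tissue.t1_ms
    ca = (
        math.cos(math.radians(seq.flip_deg))
        if seq.include_pulse_train_in_mz
        else 1.0
    )
    dt_ms = dt_us / 1000.0
    decay = 1.0 - dt_ms / t1  # one Euler step toward 1

    def euler_relax(m: float, interval_ms: float) -> float:
        n = round(interval_ms / dt_ms)
        # closed form of the Euler recurrence m <- m*decay + (1-decay)
        return 1.0 + (m - 1.0) * decay**n

    slots = seq.slot_times_ms
    m = 0.0
    result = np.zeros(seq.spokes_per_segment)
    for _ in range(max_tr):
        prev = m
        if tissue.inversion_response == "invert":
            m = -m
        else:
            m = 0.0
        m = euler_relax(m, slots[0])
        for k in range(seq.spokes_per_segment):
            result[k] = m
            m = ca * m
            if k < seq.spokes_per_segment - 1:
                m = euler_relax(m, seq.spoke_interval_ms)
        m = euler_relax(m, seq.tr_ms - slots[-1])
        if abs(m - prev) < 1e-13:
            break
    return result


def dft_forward(image: np.ndarray, coords: np.ndarray, chunk: int = 1024) -> np.ndarray:
    """Direct-summation nonuniform DFT: F(k) = sum_x f(x) e^{-2 pi i k.x/N}."""
    n = image.shape[0]
    p = np.arange(n) - n // 2
    pr, pc = np.meshgrid(p, p, indexing="ij")
    flat = coords.reshape(-1, 2)
    out = np.empty(flat.shape[0], dtype=complex)
    img = image.astype(complex).ravel()
    xr, xc = pr.ravel(), pc.ravel()
    for i in range(0, flat.shape[0], chunk):
        k = flat[i : i + chunk]
        phase = np.exp(-2j * np.pi * (np.outer(k[:, 0], xr) + np.outer(k[:, 1], xc)) / n)
        out[i : i + chunk] = phase @ img
    return out.reshape(coords.shape[:-1])


def dft_adjoint(samples: np.ndarray, coords: np.ndarray, n: int, chunk: int = 1024) -> np.ndarray:
    """Direct-summation adjoint: f(x) = sum_k s(k) e^{+2 pi i k.x/N}."""
    p = np.arange(n) - n // 2
    pr, pc = np.meshgrid(p, p, indexing="ij")
    xr, xc = pr.ravel(), pc.ravel()
    flat_k = coords.reshape(-1, 2)
    flat_s = np.asarray(samples, dtype=complex).reshape(-1)
    out = np.zeros(n * n, dtype=complex)
    for i in range(0, flat_k.shape[0], chunk):
        k = flat_k[i : i + chunk]
        phase = np.exp(2j * np.pi * (np.outer(xr, k[:, 0]) + np.outer(xc, k[:, 1])) / n)
        out += phase @ flat_s[i : i + chunk]
    return out.reshape(n, n)


def antialiased_disc(n: int, radius: float, supersample: int = 8) -> np.ndarray:
    """Unit disc centered on pixel (n//2, n//2), rasterized with subpixel
    area weighting so its spectrum matches the continuous disc transform."""
    c = n // 2
    s = supersample
    rr, cc = np.mgrid[0 : n * s, 0 : n * s].astype(float)
    rr = (rr + 0.5) / s - 0.5
    cc = (cc + 0.5) / s - 0.5
    inside = (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
    return inside.reshape(n, s, n, s).mean(axis=(1, 3))


def disc_transform(coords: np.ndarray, radius: float, n: int) -> np.ndarray:
    """Closed-form Fourier transform of the centered disc at the sample
    coordinates (cycles/FOV), including the square-pixel aperture factor:
    pi R^2 * jinc(2 pi |k| R / N) * sinc(k_r/N) * sinc(k_c/N)."""
    q = np.hypot(coords[..., 0], coords[..., 1]) / n
    z = 2.0 * np.pi * q * radius
    safe = np.where(z > 0, z, 1.0)
    jinc = np.where(z > 0, 2.0 * j1(safe) / safe, 1.0)
    return (
        np.pi
        * radius**2
        * jinc
        * np.sinc(coords[..., 0] / n)
        * np.sinc(coords[..., 1] / n)
    )
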