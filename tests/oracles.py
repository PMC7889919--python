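"""Independent reference implementations used only by the test suite.

The 2x2 transfer-matrix product below solves the same stratified-medium
problem as the package's cascade-reflection recursion but through an
entirely different algebraic route (interface/propagation matrix chain),
so agreement between the two is a genuine cross-check.
"""

from __future__ import annotations

import cmath
import math

import numpy as np

C0 = 299792458.0


def _indices(eps_list, eps_inc=1.0 + 0j):
    return [cmath.sqrt(complex(eps_inc))] + [cmath.sqrt(complex(e)) for e in eps_list]


def _interface(n_a, n_b):
    r = (n_a - n_b) / (n_a + n_b)
    t = 2 * n_a / (n_a + n_b)
    return np.array([[1, r], [r, 1]], dtype=complex) / t


def _propagation(k, h):
    return np.array([[cmath.exp(1j * k * h), 0], [0, cmath.exp(-1j * k * h)]])


def tm_solve(eps_list, thicknesses, frequency, eps_inc=1.0 + 0j):
    """Transfer-matrix solution of an N-layer stack (last semi-infinite).

    Returns (r0, tc, amplitudes) with amplitudes[j] = (F, B) at the top of
    tissue medium j (relative to the incident amplitude).
    """
    n = _indices(eps_list, eps_inc)
    k0 = 2 * math.pi * frequency / C0
    k = [k0 * ni for ni in n]
    n_media = len(eps_list)

    chain = []
    for j in range(n_media):
        chain.append(_interface(n[j], n[j + 1]))
        if j + 1 < n_media:
            chain.append(_propagation(k[j + 1], thicknesses[j]))
    m_total = np.eye(2, dtype=complex)
    for m in chain:
        m_total = m_total @ m
    r0 = m_total[1, 0] / m_total[0, 0]
    f_terminal = np.array([1.0 / m_total[0, 0], 0.0], dtype=complex)

    # suffixes[i] = product of chain[i:]; applied to the terminal state it
    # yields the amplitudes just below interface (i-1)//2
    suffixes = [np.eye(2, dtype=complex)]
    for m in reversed(chain):
        suffixes.append(m @ suffixes[-1])
    suffixes.reverse()
    amps = []
    for j in range(n_media):
        amp = suffixes[2 * j + 1] @ f_terminal
        amps.append((amp[0], amp[1]))
    return r0, 1.0 - abs(r0) ** 2, amps


def tm_field(eps_list, thicknesses, frequency, depth, eps_inc=1.0 + 0j):
    """E(depth)/E0+ at a global depth into the tissue."""
    n = _indices(eps_list, eps_inc)
    k0 = 2 * math.pi * frequency / C0
    _, _, amps = tm_solve(eps_list, thicknesses, frequency, eps_inc)
    z_top = 0.0
    for j, h in enumerate(thicknesses):
        if depth <= z_top + h or j == len(eps_list) - 1:
            f, b = amps[j]
            zloc = depth - z_top
            kj = k0 * n[j + 1]
            return f * cmath.exp(-1j * kj * zloc) + b * cmath.exp(1j * kj * zloc)
        z_top += h
    f, b = amps[-1]
    kj = k0 * n[-1]
    return f * cmath.exp(-1j * kj * (depth - z_top))


def random_stack(rng, n_layers=None):
    """Random 2-6 layer absorbing stack as (eps_list, thicknesses)."""
    n_layers = n_layers or int(rng.integers(2, 7))
    eps = []
    ths = []
    for i in range(n_layers):
        re = rng.uniform(1.5, 50.0)
        im = rng.uniform(0.0, 30.0)
        eps.append(complex(re, -im))
        ths.append(math.inf if i == n_layers - 1 else rng.uniform(1e-5, 5e-3))
    # keep the terminal layer lossy so all power is eventually absorbed
    eps[-1] = complex(eps[-1].real, -max(-eps[-1].imag, 0.5))
    return eps, ths
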