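"""Independent brute-force discrete-Fourier oracle.

Deliberately O(N^2) and written directly from the transform definition,
with no FFT calls and no imports from rrmkit, so the test suite checks the
package's spectral path against a second derivation rather than against
itself.
"""

import cmath

import numpy as np


def dft_direct(x):
    """Full complex DFT by direct summation: X_k = sum_j x_j e^{-2 pi i jk/n}."""
    x = list(x)
    n = len(x)
    out = []
    for k in range(n):
        acc = 0j
        for j, value in enumerate(x):
            acc += value * cmath.exp(-2j * cmath.pi * j * k / n)
        out.append(acc)
    return np.array(out)


def one_sided_amplitude_phase(values, n_points):
    """Mean-removed, zero-padded one-sided amplitude/phase via the direct DFT."""
    values = np.asarray(values, float)
    x = list(values - values.mean()) + [0.0] * (n_points - len(values))
    transform = dft_direct(x)[: n_points // 2 + 1]
    return np.abs(transform), np.angle(transform)
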