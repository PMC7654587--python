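"""Numba kernels for the 3D force-directed layout. Internal."""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _repulsion(X, k2):
    n = X.shape[0]
    disp = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            dx = X[i, 0] - X[j, 0]
            dy = X[i, 1] - X[j, 1]
            dz = X[i, 2] - X[j, 2]
            d2 = dx * dx + dy * dy + dz * dz + 1e-12
            f = k2 / d2
            disp[i, 0] += dx * f
            disp[i, 1] += dy * f
            disp[i, 2] += dz * f
            disp[j, 0] -= dx * f
            disp[j, 1] -= dy * f
            disp[j, 2] -= dz * f
    return disp


@njit(cache=True, fastmath=True)
def _attraction(X, eu, ev, w, k, disp):
    for e in range(eu.shape[0]):
        i = eu[e]
        j = ev[e]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz) + 1e-12
        f = w[e] * d / k
        disp[i, 0] -= dx * f
        disp[i, 1] -= dy * f
        disp[i, 2] -= dz * f
        disp[j, 0] += dx * f
        disp[j, 1] += dy * f
        disp[j, 2] += dz * f
    return disp


@njit(cache=True, fastmath=True)
def _apply(X, disp, t):
    n = X.shape[0]
    for i in range(n):
        d = np.sqrt(disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2) + 1e-12
        step = min(d, t)
        X[i, 0] += disp[i, 0] / d * step
        X[i, 1] += disp[i, 1] / d * step
        X[i, 2] += disp[i, 2] / d * step
    return X
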