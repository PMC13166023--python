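"""Numba kernels for EMD sifting.

Everything here operates on plain float64 arrays so the hot loop
(envelope spline fits inside the sift iteration) stays allocation-light
and jit-compilable. Public wrappers live in :mod:`ssrime.decomposition`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mean_envelope", "sift_kernel", "count_extrema", "count_zero_crossings"]


@njit(cache=True)
def _find_extrema(x):
    """Indices of interior local maxima and minima.

    Plateaus are collapsed to their midpoint so a flat-topped peak counts
    once. Endpoints are never extrema (mirroring supplies the boundary).
    """
    n = x.shape[0]
    max_idx = np.empty(n, dtype=np.int64)
    min_idx = np.empty(n, dtype=np.int64)
    n_max = 0
    n_min = 0
    prev_slope = 0  # sign of last non-zero difference
    plateau_start = -1
    for i in range(1, n):
        d = x[i] - x[i - 1]
        if d > 0.0:
            slope = 1
        elif d < 0.0:
            slope = -1
        else:
            slope = 0
        if slope == 0:
            if plateau_start < 0:
                plateau_start = i - 1
            continue
        if prev_slope > 0 and slope < 0:
            idx = i - 1 if plateau_start < 0 else (plateau_start + i - 1) // 2
            max_idx[n_max] = idx
            n_max += 1
        elif prev_slope < 0 and slope > 0:
            idx = i - 1 if plateau_start < 0 else (plateau_start + i - 1) // 2
            min_idx[n_min] = idx
            n_min += 1
        prev_slope = slope
        plateau_start = -1
    return max_idx[:n_max], min_idx[:n_min]


@njit(cache=True)
def _natural_spline(t, y, tq):
    """Natural cubic spline through (t, y), evaluated at tq.

    t strictly increasing. Thomas algorithm for the second derivatives;
    linear interpolation when only two knots are given.
    """
    m = t.shape[0]
    nq = tq.shape[0]
    out = np.empty(nq)
    if m == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        for i in range(nq):
            out[i] = y[0] + slope * (tq[i] - t[0])
        return out
    # second derivatives M[0]=M[m-1]=0 (natural)
    h = np.empty(m - 1)
    for i in range(m - 1):
        h[i] = t[i + 1] - t[i]
    # tridiagonal system of size m-2
    a = np.empty(m - 2)  # sub
    b = np.empty(m - 2)  # diag
    c = np.empty(m - 2)  # super
    d = np.empty(m - 2)  # rhs
    for i in range(m - 2):
        a[i] = h[i]
        b[i] = 2.0 * (h[i] + h[i + 1])
        c[i] = h[i + 1]
        d[i] = 6.0 * ((y[i + 2] - y[i + 1]) / h[i + 1] - (y[i + 1] - y[i]) / h[i])
    # forward sweep
    for i in range(1, m - 2):
        w = a[i] / b[i - 1]
        b[i] -= w * c[i - 1]
        d[i] -= w * d[i - 1]
    M = np.zeros(m)
    if m > 2:
        M[m - 2] = d[m - 3] / b[m - 3]
        for i in range(m - 4, -1, -1):
            M[i + 1] = (d[i] - c[i] * M[i + 2]) / b[i]
    # evaluate; tq is sorted ascending in our use, walk the knot index
    j = 0
    for i in range(nq):
        tv = tq[i]
        while j < m - 2 and tv > t[j + 1]:
            j += 1
        hj = h[j]
        A = (t[j + 1] - tv) / hj
        B = (tv - t[j]) / hj
        out[i] = (
            A * y[j]
            + B * y[j + 1]
            + ((A * A * A - A) * M[j] + (B * B * B - B) * M[j + 1]) * hj * hj / 6.0
        )
    return out


@njit(cache=True)
def _mirrored_envelope(idx, val, n):
    """Spline envelope through extrema, mirroring two extrema at each end."""
    m = idx.shape[0]
    # mirror about the first/last sample
    k = 2 if m >= 2 else m
    t = np.empty(m + 2 * k)
    y = np.empty(m + 2 * k)
    for i in range(k):
        t[k - 1 - i] = -float(idx[i]) if idx[i] > 0 else -float(i + 1)
        y[k - 1 - i] = val[i]
    for i in range(m):
        t[k + i] = float(idx[i])
        y[k + i] = val[i]
    last = float(n - 1)
    for i in range(k):
        src = m - 1 - i
        ref = 2.0 * last - float(idx[src])
        t[k + m + i] = ref if ref > last else last + float(i + 1)
        y[k + m + i] = val[src]
    # enforce strict monotonicity of knots (mirroring can collide when an
    # extremum sits on a boundary sample)
    for i in range(1, t.shape[0]):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 0.5
    tq = np.arange(n).astype(np.float64)
    return _natural_spline(t, y, tq)


@njit(cache=True)
def mean_envelope(x):
    """Mean of upper/lower cubic-spline envelopes; flag=False if degenerate."""
    n = x.shape[0]
    max_idx, min_idx = _find_extrema(x)
    if max_idx.shape[0] < 2 or min_idx.shape[0] < 2:
        return np.zeros(n), False
    upper = _mirrored_envelope(max_idx, x[max_idx], n)
    lower = _mirrored_envelope(min_idx, x[min_idx], n)
    return 0.5 * (upper + lower), True


@njit(cache=True)
def count_extrema(x):
    max_idx, min_idx = _find_extrema(x)
    return max_idx.shape[0], min_idx.shape[0]


@njit(cache=True)
def count_zero_crossings(x):
    n = x.shape[0]
    count = 0
    prev = 0.0
    have_prev = False
    for i in range(n):
        v = x[i]
        if v == 0.0:
            continue
        if have_prev and (v > 0.0) != (prev > 0.0):
            count += 1
        prev = v
        have_prev = True
    return count


@njit(cache=True)
def sift_kernel(x, sd_threshold, max_iters):
    """One full sift: iterate mean-envelope subtraction until the Cauchy
    SD criterion falls below ``sd_threshold`` or ``max_iters`` is reached.

    Returns (h, status): status 0 = converged, 1 = max_iters reached,
    2 = degenerate (fewer than two maxima or two minima on entry).
    """
    h = x.copy()
    env, ok = mean_envelope(h)
    if not ok:
        return h, 2
    for _ in range(max_iters):
        denom = 0.0
        num = 0.0
        for i in range(h.shape[0]):
            denom += h[i] * h[i]
            num += env[i] * env[i]
        h = h - env
        if denom == 0.0 or num / denom < sd_threshold:
            return h, 0
        env, ok = mean_envelope(h)
        if not ok:
            return h, 0
    return h, 1
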