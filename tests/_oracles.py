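"""Independent brute-force oracles used to cross-check the production code.

Everything here is written as literally as possible — explicit loops,
explicit padding, full enumeration — and deliberately shares no helper
code with the package.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# windowed-sum (convolution) oracles


def truncated_gaussian_2d(sigma: float) -> np.ndarray:
    radius = max(1, int(round(2.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g = g / g.sum()
    return np.outer(g, g)


def conv_bruteforce(arr: np.ndarray, sigma: float) -> np.ndarray:
    """Quadruple-loop windowed sum with symmetric (reflect) borders."""
    kernel = truncated_gaussian_2d(sigma)
    r = kernel.shape[0] // 2
    padded = np.pad(np.asarray(arr, dtype=float), r, mode="symmetric")
    h, w = arr.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    acc += kernel[di + r, dj + r] * padded[i + di + r, j + dj + r]
            out[i, j] = acc
    return out


def e_fields_bruteforce(image, bias, c1, c2, sigma):
    """e_i(x) = sum_y K(y-x) (I(x) - b(y) c_i)^2 by direct summation."""
    kernel = truncated_gaussian_2d(sigma)
    r = kernel.shape[0] // 2
    bpad = np.pad(np.asarray(bias, dtype=float), r, mode="symmetric")
    h, w = image.shape
    e1 = np.zeros((h, w))
    e2 = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    k = kernel[di + r, dj + r]
                    b = bpad[i + di + r, j + dj + r]
                    e1[i, j] += k * (image[i, j] - b * c1) ** 2
                    e2[i, j] += k * (image[i, j] - b * c2) ** 2
    return e1, e2


def grad_central(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hand-rolled np.gradient equivalent (central, one-sided at edges)."""
    h, w = f.shape
    gy = np.zeros_like(f)
    gx = np.zeros_like(f)
    for i in range(h):
        for j in range(w):
            gy[i, j] = (f[min(i + 1, h - 1), j] - f[max(i - 1, 0), j]) / (
                min(i + 1, h - 1) - max(i - 1, 0))
            gx[i, j] = (f[i, min(j + 1, w - 1)] - f[i, max(j - 1, 0)]) / (
                min(j + 1, w - 1) - max(j - 1, 0))
    return gy, gx


def lic_energy_bruteforce(image, phi, bias, c1, c2, sigma, nu, mu, eps):
    """Literal evaluation of the full LIC energy."""
    e1, e2 = e_fields_bruteforce(image, bias, c1, c2, sigma)
    m1 = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))
    data = np.sum(e1 * m1 + e2 * (1.0 - m1))
    gy, gx = grad_central(phi)
    mag = np.sqrt(gy ** 2 + gx ** 2)
    delta = (eps / np.pi) / (eps ** 2 + phi ** 2)
    length = np.sum(delta * mag)
    pw = np.where(mag <= 1.0,
                  (1.0 - np.cos(2.0 * np.pi * mag)) / (2.0 * np.pi) ** 2,
                  0.5 * (mag - 1.0) ** 2)
    return float(data + nu * length + mu * np.sum(pw))


def cluster_means_bruteforce(image, phi, bias, sigma, eps):
    """Direct-summation closed form for c1, c2."""
    kb = conv_bruteforce(bias, sigma)
    kb2 = conv_bruteforce(bias * bias, sigma)
    m1 = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))
    out = []
    for m in (m1, 1.0 - m1):
        out.append(np.sum(kb * image * m) / np.sum(kb2 * m))
    return out[0], out[1]


def bias_bruteforce(image, phi, c1, c2, sigma, eps, floor):
    """Per-pixel closed form for b by direct summation."""
    m1 = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))
    j1 = c1 * m1 + c2 * (1.0 - m1)
    j2 = c1 ** 2 * m1 + c2 ** 2 * (1.0 - m1)
    num = conv_bruteforce(image * j1, sigma)
    den = conv_bruteforce(j2, sigma)
    return np.maximum(num / den, floor)


# ---------------------------------------------------------------------------
# polynomial-fit oracle


def polyfit_normal_equations(t: np.ndarray, u: np.ndarray, order: int):
    """Solve the normal equations of ordinary least squares directly."""
    a = np.vander(t, order + 1, increasing=True)
    coeffs = np.linalg.solve(a.T @ a, a.T @ u)
    return coeffs, a @ coeffs


# ---------------------------------------------------------------------------
# exact-test enumeration oracles


def mann_whitney_u(a, b) -> float:
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact_p(a, b) -> float:
    """Exact two-sided p by enumerating every group assignment."""
    a = list(a)
    b = list(b)
    pooled = a + b
    m = len(a)
    u_obs = mann_whitney_u(a, b)
    n_total = comb(len(pooled), m)
    count_le = 0
    count_ge = 0
    for idx in combinations(range(len(pooled)), m):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mann_whitney_u(ga, gb)
        if u <= u_obs + 1e-12:
            count_le += 1
        if u >= u_obs - 1e-12:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / n_total)


def wilcoxon_exact_p(diffs) -> float:
    """Exact two-sided p by enumerating all 2^n sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)  # no tied magnitudes assumed
    w_obs = ranks[d > 0].sum()
    count_le = 0
    count_ge = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-12:
            count_le += 1
        if w >= w_obs - 1e-12:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / 2 ** n)


def kruskal_h_by_ranks(groups) -> float:
    """H from the rank-sum formula with tie correction, computed literally."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        r = ranks[start:start + k].sum()
        h += r * r / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie
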