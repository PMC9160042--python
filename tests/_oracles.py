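"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain double loops over pixels/bins, sharing
no code path with the package, so agreement is a genuine cross-check.
"""

import math

import numpy as np

from aggrgan.aggregation import gaussian_kernel1d


def ssim_oracle(x, y, c1, c2):
    fx = x.astype(float).ravel()
    fy = y.astype(float).ravel()
    n = fx.size
    mx = sum(fx) / n
    my = sum(fy) / n
    vx = sum((v - mx) ** 2 for v in fx) / n
    vy = sum((v - my) ** 2 for v in fy) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(fx, fy)) / n
    return ((2 * mx * my + c1) * (2 * cov + c2)
            / ((mx * mx + my * my + c1) * (vx + vy + c2)))


def psnr_oracle(x, y):
    fx = x.astype(float)
    fy = y.astype(float)
    m, n = fx.shape
    mse = 0.0
    for i in range(m):
        for j in range(n):
            mse += (fx[i, j] - fy[i, j]) ** 2
    mse /= m * n
    if mse == 0:
        return math.inf
    return 20.0 * math.log10(255.0 / math.sqrt(mse))


def histogram_oracle(x):
    probs = [0.0] * 256
    flat = x.ravel()
    for v in flat:
        probs[int(v)] += 1.0
    return np.array([p / flat.size for p in probs])


def kl_oracle(p, q, eps):
    ps = [(v + eps) for v in p]
    qs = [(v + eps) for v in q]
    sp, sq = sum(ps), sum(qs)
    total = 0.0
    for a, b in zip(ps, qs):
        a, b = a / sp, b / sq
        total += a * math.log(a / b)
    return total


def sd_oracle(x, y):
    fx = x.astype(float)
    fy = y.astype(float)
    m, n = fx.shape

    def delta(f, i, j):
        up = f[i - 1, j] if i > 0 else f[i, j]
        left = f[i, j - 1] if j > 0 else f[i, j]
        return 2 * f[i, j] - up - left

    total = 0.0
    for i in range(m):
        for j in range(n):
            total += abs(delta(fx, i, j) - delta(fy, i, j))
    nabla = total / (m * n)
    if nabla == 0:
        return math.inf
    return 10.0 * math.log10(255.0 ** 2 / nabla)


# ---------------------------------------------------------------------------
# aggregation reference path
# ---------------------------------------------------------------------------

def _reflect(i, n):
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        if i >= n:
            i = 2 * n - 1 - i
    return i


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


def sobel_oracle(f):
    m, n = f.shape
    out = np.zeros((m, n))
    for r in range(m):
        for c in range(n):
            sx = sy = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    v = f[_reflect(r + dr, m), _reflect(c + dc, n)]
                    sx += _SOBEL_X[dr + 1, dc + 1] * v
                    sy += _SOBEL_Y[dr + 1, dc + 1] * v
            out[r, c] = math.sqrt(sx * sx + sy * sy)
    return out


def gaussian_oracle(a, sigma):
    k = gaussian_kernel1d(sigma)
    r = len(k) // 2
    m, n = a.shape
    t = np.zeros_like(a)
    for i in range(m):
        for j in range(n):
            t[i, j] = sum(k[d + r] * a[_reflect(i + d, m), j] for d in range(-r, r + 1))
    out = np.zeros_like(a)
    for i in range(m):
        for j in range(n):
            out[i, j] = sum(k[d + r] * t[i, _reflect(j + d, n)] for d in range(-r, r + 1))
    return out


def aggregate_oracle(images, scores, sigma):
    """Naive per-pixel version of the full aggregation of three candidates."""
    order = sorted(range(3), key=lambda i: (-scores[i], i))
    i, j = order[0], order[1]
    f1 = images[i].astype(float)
    f2 = images[j].astype(float)
    m1, m2 = scores[i], scores[j]
    if math.isinf(m1) or math.isinf(m2):
        m1, m2 = (1.0, 1.0) if m1 == m2 else ((2.0, 1.0) if m1 > m2 else (1.0, 2.0))
    m1, m2 = max(m1, 0.0), max(m2, 0.0)
    if m1 == 0 and m2 == 0:
        m1 = m2 = 1.0
    g1 = gaussian_oracle(sobel_oracle(f1), sigma)
    g2 = gaussian_oracle(sobel_oracle(f2), sigma)
    m, n = f1.shape
    out = np.zeros((m, n), dtype=np.uint8)
    for r in range(m):
        for c in range(n):
            a = g1[r, c] * m1
            b = g2[r, c] * m2
            w1 = a / (a + b) if (a + b) > 0 else m1 / (m1 + m2)
            out[r, c] = np.uint8(np.rint(w1 * f1[r, c] + (1 - w1) * f2[r, c]))
    return out
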