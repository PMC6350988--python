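"""Naive, loop-based HOG reference used as an independent oracle.

Implements the same descriptor dialect as the package — centred
differences with replicated borders, unsigned bilinear orientation
voting, clamped bilinear spatial voting within blocks, L2-Hys with the
soft magnitude gain — but with plain Python loops and no shared code, so
agreement with the vectorized implementation is meaningful.
"""

import math

import numpy as np


def naive_hog(img, window=49, cell=7, block=14, stride=7, n_bins=9,
              clip=0.2, signed=False, block_gain_eps=0.02):
    img = np.asarray(img, dtype=float)
    assert img.shape == (window, window)
    period = 360.0 if signed else 180.0
    width = period / n_bins
    cpb = block // cell
    nb = (window - block) // stride + 1

    def pix(r, c):
        r = min(max(r, 0), window - 1)
        c = min(max(c, 0), window - 1)
        return img[r, c]

    # per-pixel gradient, magnitude, orientation
    mag = np.zeros((window, window))
    ang = np.zeros((window, window))
    for r in range(window):
        for c in range(window):
            gx = pix(r, c + 1) - pix(r, c - 1)
            gy = pix(r + 1, c) - pix(r - 1, c)
            mag[r, c] = math.hypot(gx, gy)
            ang[r, c] = math.degrees(math.atan2(gy, gx)) % period

    cell_centers = [(ci + 0.5) * cell for ci in range(cpb)]

    def spatial_weight(pos, ci):
        if ci == 0 and pos < cell_centers[0]:
            return 1.0
        if ci == cpb - 1 and pos > cell_centers[-1]:
            return 1.0
        return max(0.0, min(1.0, 1.0 - abs(pos - cell_centers[ci]) / cell))

    out = []
    for by in range(nb):
        for bx in range(nb):
            hist = [[[0.0] * n_bins for _ in range(cpb)] for _ in range(cpb)]
            for i in range(block):
                for j in range(block):
                    r, c = by * stride + i, bx * stride + j
                    m = mag[r, c]
                    if m == 0.0:
                        continue
                    t = ang[r, c] / width - 0.5
                    b0 = math.floor(t)
                    w1 = t - b0
                    b1 = (b0 + 1) % n_bins
                    b0 = b0 % n_bins
                    for ci in range(cpb):
                        wy = spatial_weight(i + 0.5, ci)
                        if wy == 0.0:
                            continue
                        for cj in range(cpb):
                            wx = spatial_weight(j + 0.5, cj)
                            if wx == 0.0:
                                continue
                            w = wy * wx * m
                            hist[ci][cj][b0] += w * (1.0 - w1)
                            hist[ci][cj][b1] += w * w1
            v = [hist[ci][cj][k]
                 for ci in range(cpb) for cj in range(cpb)
                 for k in range(n_bins)]
            raw_norm = math.sqrt(sum(x * x for x in v))
            if raw_norm < 1e-12:
                out.extend([0.0] * len(v))
                continue
            v = [min(x / raw_norm, clip) for x in v]
            n2 = math.sqrt(sum(x * x for x in v))
            if n2 < 1e-12:
                out.extend([0.0] * len(v))
                continue
            gain = raw_norm / (raw_norm + block_gain_eps) if block_gain_eps > 0 else 1.0
            out.extend([x / n2 * gain for x in v])
    return np.array(out)
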