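"""Independent brute-force oracles: literal per-pixel / per-element
transcriptions of the defining formulas, kept deliberately naive and
separate from the implementation they check."""

import math

import numpy as np


def de_pixel(window3x3):
    """Differential excitation of one 3x3 window, summed term by term."""
    w = np.asarray(window3x3, dtype=float)
    xc = w[1, 1]
    total = 0.0
    for i in range(3):
        for j in range(3):
            if (i, j) != (1, 1):
                total += w[i, j] - xc
    return math.atan(total / xc)


def de_map(image):
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    out = np.empty((h - 2, w - 2))
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            out[i - 1, j - 1] = de_pixel(img[i - 1 : i + 2, j - 1 : j + 2])
    return out


# 8 grid neighbours of a 3x3 window in circular order (matches the
# R=1, P=8 sampling convention)
_NEIGH8 = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


def lbp_riu2_pixel(window3x3):
    """riu2 code of one pixel: threshold, count transitions, sum bits."""
    w = np.asarray(window3x3, dtype=float)
    gc = w[1, 1]
    bits = [1 if w[1 + dr, 1 + dc] - gc >= 0 else 0 for dr, dc in _NEIGH8]
    u = abs(bits[-1] - bits[0])
    for i in range(1, len(bits)):
        u += abs(bits[i] - bits[i - 1])
    return sum(bits) if u <= 2 else 9


def lbp_map(image):
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    out = np.empty((h - 2, w - 2), dtype=int)
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            out[i - 1, j - 1] = lbp_riu2_pixel(img[i - 1 : i + 2, j - 1 : j + 2])
    return out


def joint_histogram(lbp, de, m=10, n=10):
    """Double-loop joint counting of (LBP code, |DE| bin) pairs."""
    lbp = np.asarray(lbp)
    de = np.asarray(de)
    hist = np.zeros((m, n))
    h, w = lbp.shape
    for i in range(h):
        for j in range(w):
            bin_n = int(abs(de[i, j]) / (math.pi / 2) * n)
            bin_n = min(bin_n, n - 1)
            hist[lbp[i, j], bin_n] += 1
    return hist / (h * w)


def wb_ltp_pixel(window3x3, t):
    """Ternary relative-contrast coding of one pixel -> (up, low)."""
    w = np.asarray(window3x3, dtype=float)
    gc = w[1, 1]
    up = low = 0
    for i, (dr, dc) in enumerate(_NEIGH8):
        ratio = (w[1 + dr, 1 + dc] - gc) / gc
        if ratio > t:
            up += 2**i
        elif ratio < -t:
            low += 2**i
    return up, low


def spearman(a, b):
    """Rank Pearson with midranks, from first principles."""

    def midranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x)
        ranks = np.empty(len(x))
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = midranks(a), midranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / math.sqrt((ra**2).sum() * (rb**2).sum()))


def corrected_t(diffs, n_train, n_test):
    """Scalar transcription of the corrected resampled t statistic."""
    d = list(map(float, diffs))
    k = len(d)
    mean = sum(d) / k
    var = sum((x - mean) ** 2 for x in d) / (k - 1)
    return mean / math.sqrt(var * (1.0 / k + n_test / n_train))
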