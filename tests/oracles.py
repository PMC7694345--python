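"""Independent brute-force oracles for the numerical test suite.

Everything here is written as plain nested loops (or dense linear algebra)
straight from the mathematical definitions, deliberately sharing no code
with the package, so agreement is evidence of correctness rather than of
shared bugs.  Only usable at tiny sizes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pad_symmetric(img: np.ndarray, m: int) -> np.ndarray:
    return np.pad(img, m, mode="symmetric")


def conv2d_sym_loop(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution (kernel flipped), symmetric padding, 'same'."""
    kh, kw = kernel.shape
    mh, mw = kh // 2, kw // 2
    padded = np.pad(img, ((mh, mh), (mw, mw)), mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    H, W = img.shape
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * padded[i + mh - (a - mh), j + mw - (b - mw)]
            out[i, j] = acc
    return out


def circular_conv_loop(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular (periodic) convolution with the kernel anchored at (0,0),
    matching zero-padding the kernel to the image size and multiplying
    DFTs."""
    H, W = img.shape
    kh, kw = kernel.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * img[(i - a) % H, (j - b) % W]
            out[i, j] = acc
    return out


def activity_loop(stack: np.ndarray) -> np.ndarray:
    U, H, W = stack.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            out[i, j] = sum(abs(stack[u, i, j]) for u in range(U))
    return out


def window_mean_loop(arr: np.ndarray, m: int) -> np.ndarray:
    padded = pad_symmetric(arr, m) if m > 0 else arr
    H, W = arr.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for a in range(-m, m + 1):
                for b in range(-m, m + 1):
                    acc += padded[i + m + a, j + m + b]
            out[i, j] = acc / (2 * m + 1) ** 2
    return out


# ---------------------------------------------------------------------------
# metrics


def quantize_loop(img: np.ndarray, n: int = 256) -> np.ndarray:
    return np.array(
        [[math.floor(v * (n - 1) + 0.5) for v in row] for row in img], dtype=int
    )


def entropy_loop(img: np.ndarray, n: int = 256) -> float:
    q = quantize_loop(img, n)
    counts: dict[int, int] = {}
    for v in q.ravel():
        counts[v] = counts.get(v, 0) + 1
    total = q.size
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def mi_pair_loop(x: np.ndarray, y: np.ndarray, n: int = 256) -> float:
    qx, qy = quantize_loop(x, n), quantize_loop(y, n)
    joint: dict[tuple[int, int], int] = {}
    mx: dict[int, int] = {}
    my: dict[int, int] = {}
    for a, b in zip(qx.ravel(), qy.ravel()):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        mx[a] = mx.get(a, 0) + 1
        my[b] = my.get(b, 0) + 1
    total = qx.size
    mi = 0.0
    for (a, b), c in joint.items():
        pxy = c / total
        mi += pxy * math.log2(pxy / ((mx[a] / total) * (my[b] / total)))
    return mi


def mutual_information_loop(a, b, f, n: int = 256) -> float:
    return mi_pair_loop(a, f, n) + mi_pair_loop(b, f, n)


def _sobel_loop(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    kx = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], float)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], float)
    gx = conv2d_sym_loop(img, kx)
    gy = conv2d_sym_loop(img, ky)
    return gx, gy, np.sqrt(gx**2 + gy**2)


def _binary_stats(vals: list[int]) -> float:
    n = len(vals)
    p1 = sum(vals) / n
    h = 0.0
    for p in (p1, 1 - p1):
        if p > 0:
            h -= p * math.log2(p)
    return h


def _binary_mi_loop(xs: list[int], ys: list[int]) -> float:
    n = len(xs)
    joint: dict[tuple[int, int], int] = {}
    mx: dict[int, int] = {}
    my: dict[int, int] = {}
    for a, b in zip(xs, ys):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        mx[a] = mx.get(a, 0) + 1
        my[b] = my.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / ((mx[a] / n) * (my[b] / n)))
    return mi


def fmi_loop(a: np.ndarray, b: np.ndarray, f: np.ndarray, window: int = 3) -> float:
    feats = [_sobel_loop(x)[2] for x in (a, b, f)]
    fa, fb, fm = feats
    H, W = a.shape
    scores = []
    for i in range(H - window + 1):
        for j in range(W - window + 1):
            tiles = []
            for feat in (fa, fb, fm):
                t = [feat[i + r, j + c] for r in range(window) for c in range(window)]
                mean = sum(t) / len(t)
                tiles.append([1 if v > mean else 0 for v in t])
            ba, bb, bm = tiles
            sa, sb, sm = (_binary_stats(t) for t in tiles)
            if sm + sa <= 0 or sm + sb <= 0:
                continue
            scores.append(
                _binary_mi_loop(bm, ba) / (sm + sa) + _binary_mi_loop(bm, bb) / (sm + sb)
            )
    return sum(scores) / len(scores) if scores else 0.0


def qabf_loop(a: np.ndarray, b: np.ndarray, f: np.ndarray, T: float = 1.0) -> float:
    Gg, Kg, Sg = 0.9994, -15.0, 0.5
    Ga, Ka, Sa = 0.9879, -22.0, 0.8

    def strength_orient(img):
        gx, gy, mag = _sobel_loop(img)
        H, W = img.shape
        alpha = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                alpha[i, j] = math.atan(gy[i, j] / gx[i, j]) if gx[i, j] != 0 else math.pi / 2
        return mag, alpha

    ga, ala = strength_orient(a)
    gb, alb = strength_orient(b)
    gf, alf = strength_orient(f)

    def pres(gs, als, i, j):
        if gs[i, j] <= 1e-10:
            return 0.0
        if gf[i, j] <= 1e-10:
            return 0.0
        G = gf[i, j] / gs[i, j] if gs[i, j] > gf[i, j] else gs[i, j] / gf[i, j]
        A = 1 - abs(als[i, j] - alf[i, j]) / (math.pi / 2)
        qg = Gg / (1 + math.exp(Kg * (G - Sg)))
        qa = Ga / (1 + math.exp(Ka * (A - Sa)))
        return qg * qa

    num = den = 0.0
    H, W = a.shape
    for i in range(H):
        for j in range(W):
            wa, wb = ga[i, j] ** T, gb[i, j] ** T
            num += pres(ga, ala, i, j) * wa + pres(gb, alb, i, j) * wb
            den += wa + wb
    return num / den if den > 0 else 0.0


def _gauss_kernel_loop(n: int) -> np.ndarray:
    sd = n / 5.0
    c = (n - 1) / 2.0
    k = np.array(
        [
            [math.exp(-((i - c) ** 2 + (j - c) ** 2) / (2 * sd * sd)) for j in range(n)]
            for i in range(n)
        ]
    )
    return k / k.sum()


def _conv_valid_loop(img: np.ndarray, ker: np.ndarray) -> np.ndarray:
    H, W = img.shape
    n = ker.shape[0]
    out = np.zeros((H - n + 1, W - n + 1))
    for i in range(H - n + 1):
        for j in range(W - n + 1):
            acc = 0.0
            for a in range(n):
                for b in range(n):
                    acc += ker[n - 1 - a, n - 1 - b] * img[i + a, j + b]
            out[i, j] = acc
    return out


def vif_loop(ref: np.ndarray, dist: np.ndarray) -> float:
    sigma_nsq = 2.0
    num = den = 0.0
    r, d = ref.astype(float), dist.astype(float)
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        if min(r.shape) < n:
            break
        win = _gauss_kernel_loop(n)
        if scale > 1:
            r = _conv_valid_loop(r, win)[::2, ::2]
            d = _conv_valid_loop(d, win)[::2, ::2]
            if min(r.shape) < n:
                break
        mu1 = _conv_valid_loop(r, win)
        mu2 = _conv_valid_loop(d, win)
        s1 = np.maximum(_conv_valid_loop(r * r, win) - mu1 * mu1, 0.0)
        s2 = np.maximum(_conv_valid_loop(d * d, win) - mu2 * mu2, 0.0)
        s12 = _conv_valid_loop(r * d, win) - mu1 * mu2
        for i in range(mu1.shape[0]):
            for j in range(mu1.shape[1]):
                if s1[i, j] > 1e-10:
                    g = s12[i, j] / (s1[i, j] + 1e-10)
                    sv = s2[i, j] - g * s12[i, j]
                    s1v = s1[i, j]
                else:
                    g, sv, s1v = 0.0, s2[i, j], 0.0
                if g < 0:
                    sv, g = s2[i, j], 0.0
                sv = max(sv, 1e-10)
                num += math.log10(1 + g * g * s1v / (sv + sigma_nsq))
                den += math.log10(1 + s1v / sigma_nsq)
    return num / den if den != 0 else 1.0


# ---------------------------------------------------------------------------
# rank statistics


def _ranks_desc(scores: list[float]) -> list[float]:
    """Rank 1 = largest, ties averaged."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    ranks = [0.0] * len(scores)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def friedman_stat_loop(values: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from first principles."""
    k, N = values.shape
    ranks = np.array([_ranks_desc(list(values[:, j])) for j in range(N)]).T
    Rj = ranks.sum(axis=1)
    num = (k - 1) * float(((Rj - N * (k + 1) / 2) ** 2).sum())
    den = float((ranks**2).sum()) - N * k * (k + 1) ** 2 / 4
    return 0.0 if den <= 0 else num / den


def friedman_permutation_p(values: np.ndarray) -> float:
    """Exact permutation p-value of the Friedman statistic: permute
    method labels independently within each block."""
    k, N = values.shape
    observed = friedman_stat_loop(values)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=N):
        permuted = np.column_stack(
            [values[list(combo[j]), j] for j in range(N)]
        )
        total += 1
        if friedman_stat_loop(permuted) >= observed - 1e-12:
            count += 1
    return count / total
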