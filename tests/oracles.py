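"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literal nested loops / direct summations over
the defining formulas, deliberately sharing no code with the package paths
they check.
"""

from __future__ import annotations

import numpy as np


def naive_nlm_weights(image, center, patch_radius, search_radius, h, sigma,
                      pad_mode="reflect"):
    """Normalized patch-similarity weights for one pixel, by double loop.

    Returns (weights, indices) over candidates in row-major order."""
    img = np.asarray(image, dtype=np.float64)
    M, N = img.shape
    padded = np.pad(img, patch_radius, mode=pad_mode)

    def patch(r, c):
        return padded[r : r + 2 * patch_radius + 1, c : c + 2 * patch_radius + 1]

    r0, c0 = center
    if search_radius == "full":
        rows, cols = range(M), range(N)
    else:
        rows = range(max(0, r0 - search_radius), min(M, r0 + search_radius + 1))
        cols = range(max(0, c0 - search_radius), min(N, c0 + search_radius + 1))
    ref = patch(r0, c0)
    raw, idx = [], []
    for r in rows:
        for c in cols:
            d2 = float(np.sum((ref - patch(r, c)) ** 2))
            raw.append(np.exp(-d2 / (h * h * sigma * sigma)))
            idx.append((r, c))
    raw = np.array(raw)
    return raw / raw.sum(), np.array(idx)


def naive_nlm_filter(image, patch_radius, search_radius, h, sigma,
                     pad_mode="reflect"):
    """Pre-rounding NLM filter by quadruple loop (pixels x candidates)."""
    img = np.asarray(image, dtype=np.float64)
    M, N = img.shape
    out = np.empty((M, N))
    for r in range(M):
        for c in range(N):
            w, idx = naive_nlm_weights(img, (r, c), patch_radius, search_radius,
                                       h, sigma, pad_mode)
            out[r, c] = float(np.sum(w * img[idx[:, 0], idx[:, 1]]))
    return out


def naive_joint_histogram(original, companion, levels):
    """Per-pixel counting loop for the joint gray-level histogram."""
    a = np.asarray(original)
    b = np.asarray(companion)
    counts = np.zeros((levels, levels))
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            counts[a[r, c], b[r, c]] += 1
    return counts / a.size


def naive_local_mean(image, window):
    """Windowed mean by explicit loops over a reflect-padded image."""
    img = np.asarray(image, dtype=np.float64)
    r = window // 2
    padded = np.pad(img, r, mode="reflect")
    out = np.empty_like(img)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            out[y, x] = padded[y : y + window, x : x + window].mean()
    return np.clip(np.floor(out + 0.5), 0, None).astype(np.int64)


def naive_class_stats(p, s, t):
    """Class masses and mean vectors by direct submatrix summation."""
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    q0 = p[: s + 1, : t + 1]
    q1 = p[s + 1 :, t + 1 :]
    P0, P1 = q0.sum(), q1.sum()
    mu0 = mu1 = (np.nan, np.nan)
    if P0 > 0:
        mu0 = ((i[: s + 1] @ q0.sum(axis=1)) / P0, (q0.sum(axis=0) @ i[: t + 1]) / P0)
    if P1 > 0:
        mu1 = ((i[s + 1 :] @ q1.sum(axis=1)) / P1, (q1.sum(axis=0) @ i[t + 1 :]) / P1)
    return P0, P1, mu0, mu1


def _safe_log(x):
    return np.log(x) if x > 0 else 0.0


def naive_direct_objective(p, s, t):
    """Diagonal-boxes Kullback-Leibler sum, literally term by term."""
    P0, P1, mu0, mu1 = naive_class_stats(p, s, t)
    total = 0.0
    for i in range(0, s + 1):
        for j in range(0, t + 1):
            if p[i, j] > 0:
                if i > 0:
                    total += i * p[i, j] * (np.log(i) - _safe_log(mu0[0]))
                if j > 0:
                    total += j * p[i, j] * (np.log(j) - _safe_log(mu0[1]))
    L = p.shape[0]
    for i in range(s + 1, L):
        for j in range(t + 1, L):
            if p[i, j] > 0:
                if i > 0:
                    total += i * p[i, j] * (np.log(i) - _safe_log(mu1[0]))
                if j > 0:
                    total += j * p[i, j] * (np.log(j) - _safe_log(mu1[1]))
    return total


def naive_level_entropy_constant(p):
    """sum_ij (i p_ij log i + j p_ij log j) by direct summation."""
    L = p.shape[0]
    lg = np.array([_safe_log(k) for k in range(L)])
    i = np.arange(L, dtype=np.float64)
    return float(((i * lg)[:, None] * p).sum() + ((i * lg)[None, :] * p).sum())


def naive_offdiag_entropy(p, s, t):
    """Level-entropy mass of the two off-diagonal quadrants at (s, t)."""
    L = p.shape[0]
    lg = np.array([_safe_log(k) for k in range(L)])
    i = np.arange(L, dtype=np.float64)
    cells = (i * lg)[:, None] * p + (i * lg)[None, :] * p
    return float(cells[: s + 1, t + 1 :].sum() + cells[s + 1 :, : t + 1].sum())


def naive_reduced_objective(p, s, t):
    """Operative criterion: image-wide constant minus class moment terms,
    each piece from direct submatrix sums."""
    P0, P1, mu0, mu1 = naive_class_stats(p, s, t)
    const = naive_level_entropy_constant(p)
    val = const
    for P, mu in ((P0, mu0), (P1, mu1)):
        for m in mu:
            if P > 0 and m > 0:
                val -= P * m * np.log(m)
    return val


def naive_select_scan(p, eps=1e-12):
    """Full O(L^2) scan of the reduced objective; direct sums per vector.

    Uses numpy submatrix sums per candidate (still independent of the
    package's prefix-table path). Returns ((s, t), D)."""
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    lg = np.array([_safe_log(k) for k in range(L)])
    const = naive_level_entropy_constant(p)
    best = None
    for s in range(L):
        for t in range(L):
            q0 = p[: s + 1, : t + 1]
            q1 = p[s + 1 :, t + 1 :]
            P0, P1 = q0.sum(), q1.sum()
            if P0 <= eps or P1 <= eps:
                continue
            d = const
            for P, q, ri, ci in ((P0, q0, i[: s + 1], i[: t + 1]),
                                 (P1, q1, i[s + 1 :], i[t + 1 :])):
                for m in ((ri @ q.sum(axis=1)) / P, (q.sum(axis=0) @ ci) / P):
                    if m > 0:
                        d -= P * m * np.log(m)
            if best is None or d < best[1]:
                best = ((s, t), d)
    return best


def naive_binarize(original, companion, s, t, levels):
    """Per-pixel application of the quadrant labeling rule."""
    a = np.asarray(original)
    b = np.asarray(companion)
    p = naive_joint_histogram(a, b, levels)
    P0, P1, mu0, mu1 = naive_class_stats(p, s, t)
    out = np.zeros(a.shape, dtype=bool)
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            i, j = a[r, c], b[r, c]
            if i <= s and j <= t:
                out[r, c] = False
            elif i > s and j > t:
                out[r, c] = True
            else:
                d0 = (i - mu0[0]) ** 2 + (j - mu0[1]) ** 2 if P0 > 0 else np.inf
                d1 = (i - mu1[0]) ** 2 + (j - mu1[1]) ** 2 if P1 > 0 else np.inf
                out[r, c] = d1 < d0
    return out


def naive_scan_1d(p, criterion, maximize, eps=1e-12):
    """Generic full scan over scalar thresholds for the 1-D baselines.

    ``criterion(s)`` is evaluated at every s with both classes occupied."""
    best = None
    w = 0.0
    for s in range(p.size):
        w += p[s]
        if w <= eps or 1.0 - w <= eps:
            continue
        v = criterion(s)
        if best is None or (v > best[1] if maximize else v < best[1]):
            best = (s, v)
    return best[0]


def otsu_criterion(p):
    i = np.arange(p.size, dtype=np.float64)

    def crit(s):
        w0 = p[: s + 1].sum()
        w1 = p[s + 1 :].sum()
        m0 = (i[: s + 1] @ p[: s + 1]) / w0
        m1 = (i[s + 1 :] @ p[s + 1 :]) / w1
        return w0 * w1 * (m0 - m1) ** 2

    return crit


def kapur_criterion(p):
    def entropy(q):
        q = q[q > 0]
        q = q / q.sum()
        return float(-(q * np.log(q)).sum())

    return lambda s: entropy(p[: s + 1]) + entropy(p[s + 1 :])


def mce_criterion(p):
    i = np.arange(p.size, dtype=np.float64)

    def crit(s):
        val = 0.0
        for lo, hi in ((0, s + 1), (s + 1, p.size)):
            w = p[lo:hi].sum()
            m = i[lo:hi] @ p[lo:hi]
            if w > 0 and m > 0:
                val -= m * np.log(m / w)
        return val

    return crit


def set_cardinality_me(truth, predicted):
    """Literal set-cardinality form of the misclassification error."""
    t = np.asarray(truth, dtype=bool)
    g = np.asarray(predicted, dtype=bool)
    bo = {(r, c) for r, c in zip(*np.nonzero(~t))}
    fo = {(r, c) for r, c in zip(*np.nonzero(t))}
    bt = {(r, c) for r, c in zip(*np.nonzero(~g))}
    ft = {(r, c) for r, c in zip(*np.nonzero(g))}
    return 1.0 - (len(bo & bt) + len(fo & ft)) / (len(bo) + len(fo))
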