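"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (loops, enumeration, direct
formula transcription) and shares no code with the implementation.
"""

import numpy as np
from scipy import stats


def stouffer_brute(zs, ws):
    num = sum(float(w) * float(z) for w, z in zip(ws, zs))
    den = sum(float(w) ** 2 for w in ws) ** 0.5
    return num / den


def cochran_q_brute(effects, variances):
    u = [1.0 / v for v in variances]
    pooled = sum(ui * ei for ui, ei in zip(u, effects)) / sum(u)
    q = sum(ui * (ei - pooled) ** 2 for ui, ei in zip(u, effects))
    p = stats.chi2.sf(q, len(effects) - 1)
    return q, p


def dl_tau2_brute(effects, variances):
    q, _ = cochran_q_brute(effects, variances)
    u = [1.0 / v for v in variances]
    k = len(effects)
    denom = sum(u) - sum(ui**2 for ui in u) / sum(u)
    return max(0.0, (q - (k - 1)) / denom)


def bh_brute(p_values, q):
    """Step-up by explicit enumeration over every k."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    flags = [False] * m
    for i in range(k_star):
        flags[order[i]] = True
    return np.array(flags)


def auc_pair_counting(scores, labels):
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def flood_fill_clusters(volume, threshold=1):
    """Connected components (26-connectivity) by explicit BFS."""
    vol = np.asarray(volume)
    visited = np.zeros(vol.shape, dtype=bool)
    clusters = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in np.argwhere(vol >= threshold):
        start = tuple(start)
        if visited[start]:
            continue
        queue = [start]
        visited[start] = True
        members = []
        while queue:
            v = queue.pop()
            members.append(v)
            for off in offsets:
                nb = tuple(np.add(v, off))
                if any(c < 0 or c >= s for c, s in zip(nb, vol.shape)):
                    continue
                if not visited[nb] and vol[nb] >= threshold:
                    visited[nb] = True
                    queue.append(nb)
        clusters.append(members)
    return clusters


def pooled_two_sample_t(x, y):
    """Textbook pooled-variance two-sample t statistic."""
    nx, ny = len(x), len(y)
    sx2 = sum((v - np.mean(x)) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - np.mean(y)) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    return (np.mean(x) - np.mean(y)) / (sp2 * (1 / nx + 1 / ny)) ** 0.5


def link_pairs_brute(n):
    """All (i, j) pairs in row-major upper-triangle order."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]
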