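"""Independent brute-force reference implementations used only by tests.

These deliberately use naive loops and scalar arithmetic so they share no
code path with the package implementations they check.
"""
import numpy as np
from scipy.stats import norm


def complete_linkage_brute(d: np.ndarray):
    """O(n^3) agglomerative complete linkage from a full distance matrix.

    Ties broken by the lowest cluster-index pair.  Returns a list of
    (leaf_index_set, height) for every internal node.
    """
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    active = list(range(len(clusters)))
    merges = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                h = max(d[x, y] for x in clusters[a] for y in clusters[b])
                if best is None or h < best[0]:
                    best = (h, ai, aj)
        h, ai, aj = best
        a, b = active[ai], active[aj]
        merged = clusters[a] | clusters[b]
        clusters.append(merged)
        merges.append((merged, h))
        active = [x for x in active if x not in (a, b)] + [len(clusters) - 1]
    return merges


TRIM_Z = 2.0
FINAL_Z = 2.5


def _var_factor(q):
    return 1.0 - 2.0 * q * norm.pdf(q) / (2.0 * norm.cdf(q) - 1.0)


def de_window_z_brute(x: np.ndarray, groups_g, groups_h, w: int, robust: bool = True):
    """Per-gene intensity-difference z-scores for one group pair, computed
    gene by gene with scalar numpy calls (no sliding-window vectorisation).
    """
    n = x.shape[0]
    a = x.mean(axis=1)
    order = np.argsort(a, kind="stable")
    pos = {g: p for p, g in enumerate(order)}
    d = x[:, groups_h].mean(axis=1) - x[:, groups_g].mean(axis=1)

    n_starts = n - w + 1
    mus = np.zeros(n_starts)
    sds = np.zeros(n_starts)
    for start in range(n_starts):
        vals = np.array([d[order[start + j]] for j in range(w)])
        if robust:
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            if mad == 0:
                mus[start] = vals.mean()
                sds[start] = vals.std(ddof=1)
                continue
            centre, radius = med, TRIM_Z * 1.4826 * mad
            for _ in range(3):
                kept = vals[np.abs(vals - centre) <= radius]
                centre = kept.mean()
                scale = np.sqrt(kept.var(ddof=1) / _var_factor(TRIM_Z))
                radius = min(radius, TRIM_Z * scale)
            kept = vals[np.abs(vals - centre) <= FINAL_Z * scale]
            mus[start] = kept.mean()
            sds[start] = np.sqrt(kept.var(ddof=1) / _var_factor(FINAL_Z))
        else:
            mus[start] = vals.mean()
            sds[start] = vals.std(ddof=1)
    if robust:
        span = 5 * w
        half = span // 2
        smoothed = np.array(
            [
                np.median((sds**2)[max(0, i - half) : i + half + 1])
                for i in range(n_starts)
            ]
        )
        sds = np.sqrt(smoothed)

    z = np.zeros(n)
    for i in range(n):
        start = min(max(pos[i] - (w - 1) // 2, 0), n - w)
        z[i] = (d[i] - mus[start]) / sds[start]
    return z
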