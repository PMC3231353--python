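"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's incremental data structures: every
quantity is recomputed from scratch from the raster at every step, so they
serve as slow but transparent references.
"""

from __future__ import annotations

import numpy as np


def _circ_mean_deg(h):
    a = np.radians(np.asarray(h, dtype=np.float64))
    return float(np.degrees(np.arctan2(np.sin(a).sum(), np.cos(a).sum())) % 360.0)


def _col_dist(h1, s1, h2, s2, mode):
    dh = np.abs(np.asarray(h1, dtype=np.float64) - np.asarray(h2, dtype=np.float64)) % 360.0
    dh = np.minimum(dh, 360.0 - dh)
    if mode == "h":
        return dh
    return np.sqrt(dh**2 + (np.asarray(s1) - np.asarray(s2)) ** 2)


def brute_force_merge(hsi, seeds, dc_threshold, de_threshold, mode="hs"):
    """Exhaustive-recompute hierarchical merging; returns a label map.

    Semantics mirror the documented algorithm: greedily merge the adjacent
    pair with the smallest size-weighted mean-color distance among pairs
    satisfying both thresholds strictly (ties: lexicographic smallest id
    pair; the merged region keeps the smaller id); afterwards absorb every
    seedless region into its closest-mean-color neighbor, smallest region
    id first.  All region statistics and boundary distances are recomputed
    from the raster at every iteration.
    """
    h = np.asarray(hsi[..., 0], dtype=np.float64) % 360.0
    s = np.asarray(hsi[..., 1], dtype=np.float64)
    shape = h.shape
    label = np.full(shape, -1, dtype=np.int64)
    has_seed = {}
    for reg in seeds:
        for (r, c) in reg.pixels:
            label[r, c] = reg.id
        has_seed[reg.id] = True
    nid = max(has_seed) + 1
    for (r, c) in zip(*np.nonzero(label == -1)):
        label[r, c] = nid
        has_seed[nid] = False
        nid += 1

    def adjacency(label):
        pairs = {}
        la, lb = label[:, :-1], label[:, 1:]
        m = la != lb
        for i, j, r, c in zip(la[m], lb[m], *np.nonzero(m)):
            key = (min(i, j), max(i, j))
            pairs.setdefault(key, []).append(((r, c), (r, c + 1)))
        la, lb = label[:-1, :], label[1:, :]
        m = la != lb
        for i, j, r, c in zip(la[m], lb[m], *np.nonzero(m)):
            key = (min(i, j), max(i, j))
            pairs.setdefault(key, []).append(((r, c), (r + 1, c)))
        return {(int(a), int(b)): v for (a, b), v in pairs.items()}

    def region_stats(label):
        stats = {}
        for rid in np.unique(label):
            m = label == rid
            stats[int(rid)] = (int(m.sum()), _circ_mean_deg(h[m]), float(np.mean(s[m])))
        return stats

    while True:
        stats = region_stats(label)
        adj = adjacency(label)
        best = None
        for (i, j), plist in adj.items():
            ri, hi_, si = stats[i]
            rj, hj, sj = stats[j]
            dc = (ri * rj) / (ri + rj) * float(_col_dist(hi_, si, hj, sj, mode))
            if dc >= dc_threshold:
                continue
            d = [float(_col_dist(h[a], s[a], h[b], s[b], mode)) for a, b in plist]
            de = float(np.mean(d))
            if de >= de_threshold:
                continue
            cand = (dc, i, j)
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        _, i, j = best
        label[label == j] = i
        has_seed[i] = has_seed[i] or has_seed[j]

    while True:
        stats = region_stats(label)
        seedless = sorted(rid for rid in stats if not has_seed[rid])
        if not seedless:
            break
        rid = seedless[0]
        adj = adjacency(label)
        nbrs = [b if a == rid else a for (a, b) in adj if rid in (a, b)]
        if not nbrs:
            has_seed[rid] = True
            continue
        _, hr, sr = stats[rid]
        best = min(nbrs, key=lambda n: (float(_col_dist(hr, sr, stats[n][1], stats[n][2], "hs")), n))
        keep, dead = (rid, best) if rid < best else (best, rid)
        label[label == dead] = keep
        has_seed[keep] = has_seed[keep] or has_seed[dead]
    return label


def partition_of(label_map) -> frozenset:
    """Canonical partition (set of pixel-index sets) of a label map."""
    lab = np.asarray(label_map).ravel()
    groups = {}
    for idx, l in enumerate(lab):
        groups.setdefault(int(l), []).append(idx)
    return frozenset(frozenset(g) for g in groups.values())


def random_patch_hsi(rng, shape=(12, 12), n_patches=4, jitter=2.0):
    """Random test image: overlapping rectangular hue patches + jitter.

    Patch hues are drawn over a moderate range so some adjacent regions
    fall under the merge threshold and others do not.
    """
    h = np.full(shape, rng.uniform(0.0, 360.0))
    s = np.full(shape, 0.5)
    for _ in range(n_patches):
        r0 = rng.integers(0, shape[0] - 1)
        c0 = rng.integers(0, shape[1] - 1)
        r1 = rng.integers(r0 + 1, shape[0] + 1)
        c1 = rng.integers(c0 + 1, shape[1] + 1)
        h[r0:r1, c0:c1] = (h[r0:r1, c0:c1] + rng.uniform(-30.0, 30.0)) % 360.0
        s[r0:r1, c0:c1] = np.clip(s[r0:r1, c0:c1] + rng.uniform(-0.2, 0.2), 0.0, 1.0)
    h = (h + rng.normal(0.0, jitter, shape)) % 360.0
    i = np.full(shape, 0.5)
    return np.stack([h, s, i], axis=-1)
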