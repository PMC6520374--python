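"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library code paths they validate: component
labeling by BFS flood fill, ROC/PR areas by exhaustive pair counting and
threshold sweeps, and the two-sample t-test by the textbook formula.
"""

import numpy as np


def flood_fill_components(mask, connectivity=8):
    """Connected components by BFS; returns a list of pixel lists."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x] and not seen[y, x]:
                stack, comp = [(y, x)], []
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    comp.append((cy, cx))
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                                and mask[ny, nx] and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def brute_auroc(scores, truths):
    """Exhaustive positive-negative pair comparison, ties counted 1/2."""
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_aupr(scores, truths):
    """Exhaustive threshold sweep; step-wise precision-over-recall sum."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths)
    n_pos = truths.sum()
    area, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        called = scores >= thr
        tp = int((called & (truths == 1)).sum())
        area += (tp / n_pos - prev_recall) * (tp / called.sum())
        prev_recall = tp / n_pos
    return area


def t_test_p_value(a, b):
    """Two-sided equal-variance two-sample t-test via the t CDF."""
    from scipy.stats import t as tdist
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * tdist.sf(abs(t), na + nb - 2)


def rank_average(v):
    """Average ranks with tie sharing (1-based)."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v)
    ranks = np.empty(len(v))
    sorted_v = v[order]
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks
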