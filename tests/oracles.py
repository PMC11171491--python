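"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities from first principles (pixel
enumeration, transitive closure, exhaustive sweeps, closed forms) without
touching the implementation paths it checks.
"""

from __future__ import annotations

import math

from cxreval.geometry import PixelBox


def pixel_set(box: PixelBox) -> set[tuple[int, int]]:
    """All grid pixels covered by a box (half-open)."""
    return {
        (x, y)
        for x in range(box.x_min, box.x_max)
        for y in range(box.y_min, box.y_max)
    }


def brute_intersection(a: PixelBox, b: PixelBox) -> int:
    return len(pixel_set(a) & pixel_set(b))


def brute_jaccard(a: PixelBox, b: PixelBox) -> float:
    pa, pb = pixel_set(a), pixel_set(b)
    return len(pa & pb) / len(pa | pb)


def brute_components(boxes: list[PixelBox]) -> list[frozenset[int]]:
    """Connected components of the overlap graph by transitive closure
    over the pairwise pixel-overlap matrix."""
    n = len(boxes)
    adj = [
        [bool(pixel_set(boxes[i]) & pixel_set(boxes[j])) or i == j for j in range(n)]
        for i in range(n)
    ]
    # Floyd-Warshall style closure
    for k in range(n):
        for i in range(n):
            for j in range(n):
                adj[i][j] = adj[i][j] or (adj[i][k] and adj[k][j])
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(j for j in range(n) if adj[i][j])
        seen |= comp
        comps.append(comp)
    return comps


def brute_vote(per_model, thresholds, min_support):
    """Literal re-evaluation of the retention rules: per label, enumerate
    overlap components over all boxes, keep components with boxes from at
    least ``min_support`` distinct models, emit the highest-score member
    (ties: lowest model id, then smallest corner tuple), then drop
    sub-threshold boxes."""
    pooled = [d for dets in per_model for d in dets]
    kept = []
    labels = sorted({d.label for d in pooled}, key=lambda l: list(type(l)).index(l))
    for label in labels:
        dets = [d for d in pooled if d.label == label]
        comps = brute_components([d.box for d in dets])
        for comp in comps:
            members = [dets[i] for i in sorted(comp)]
            if len({m.model_id for m in members}) < min_support:
                continue
            best = min(members, key=lambda d: (-d.score, d.model_id, d.box.corners()))
            if best.score >= thresholds[label]:
                kept.append(best)
    return kept


def brute_youden_sweep(pos: list[float], neg: list[float]):
    """Exhaustive sweep over midpoint cuts; returns (threshold, J)."""
    distinct = sorted(set(pos) | set(neg))
    cuts = [(a + b) / 2 for a, b in zip(distinct, distinct[1:])] or [distinct[0]]
    best = None
    for t in cuts:
        j = sum(s >= t for s in pos) / len(pos) + sum(s < t for s in neg) / len(neg) - 1
        if best is None or j > best[1] or (j == best[1] and t > best[0]):
            best = (t, j)
    return best


def brute_auc(scores, labels) -> float:
    """Pairwise positive-vs-negative counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def welch_t(x: list[float], y: list[float]) -> tuple[float, float, float]:
    """Closed-form Welch statistic, degrees of freedom, and two-sided p
    (via the regularized incomplete beta through scipy's t CDF is avoided;
    uses math.erf-free survival from the t distribution series is overkill,
    so the caller compares t and df and checks p monotonically)."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (my - mx) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df, se2


def majority_loss_prob(p: float) -> float:
    """Probability that an independent per-annotator miss rate ``p`` makes
    a 2-of-3 consensus lose a true lesion: 3p^2(1-p) + p^3."""
    return 3 * p**2 * (1 - p) + p**3
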