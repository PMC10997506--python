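"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes an expected result by direct enumeration or position
marking, deliberately avoiding the library's own interval/statistic code
paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from mbrobust.genomes import GenomeSet, revcomp


def brute_force_masked_positions(
    refs: GenomeSet,
    db: GenomeSet,
    window_len: int = 150,
    step: int = 75,
    min_len: int = 75,
    max_n: int = 100,
) -> dict[str, set[int]]:
    """A db position is masked iff it lies inside some exact full-window
    occurrence (either strand).  Direct position marking, no intervals."""
    masked: dict[str, set[int]] = {c.id: set() for c in db}
    windows: list[str] = []
    for contig in refs:
        seq = contig.sequence
        for start in range(0, len(seq), step):
            sub = seq[start : start + window_len]
            if len(sub) < min_len or sub.count("N") >= max_n:
                continue
            windows.append(sub)
    for w in windows:
        targets = {w, revcomp(w)}
        for contig in db:
            seq = contig.sequence
            for t in targets:
                i = seq.find(t)
                while i != -1:
                    masked[contig.id].update(range(i, i + len(t)))
                    i = seq.find(t, i + 1)
    return masked


def fisher_enumeration(a: int, b: int, c: int, d: int, sided: str) -> float:
    """Exact Fisher p by full hypergeometric enumeration (float pmf)."""
    n1, n2, m1 = a + b, c + d, a + c
    N = n1 + n2
    denom = math.comb(N, m1)
    lo, hi = max(0, m1 - n2), min(m1, n1)
    pmf = {x: math.comb(n1, x) * math.comb(n2, m1 - x) / denom for x in range(lo, hi + 1)}
    if sided == "greater":
        return sum(p for x, p in pmf.items() if x >= a)
    if sided == "two-sided":
        cutoff = pmf[a] * (1 + 1e-9)
        return sum(p for p in pmf.values() if p <= cutoff)
    raise ValueError(sided)


def kendall_tau_b_pairs(x, y) -> float:
    """Tau-b by O(n^2) pair counting with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = tied_x = tied_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tied_x += 1
            elif dy == 0:
                tied_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(sum(c * (c - 1) / 2 for c in counts))


def fisher_method_closed_form(pvalues) -> float:
    """Survival of chi-square at even df 2m: exp(-x/2) * sum_{k<m} (x/2)^k / k!."""
    m = len(pvalues)
    x = -2.0 * sum(math.log(p) for p in pvalues)
    half = x / 2.0
    return math.exp(-half) * sum(half**k / math.factorial(k) for k in range(m))


def bh_step_up(pvalues) -> list[float]:
    """Hand step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def auroc_rank_statistic(scores, labels) -> float:
    """U / (n1 * n0) via pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))


def aupr_step_sum(scores, labels) -> float:
    """Brute-force stepwise precision-recall summation (no score ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores)
    labels = labels[order]
    n_pos = int(labels.sum())
    tp = 0
    area = 0.0
    prev_recall = 0.0
    for i, lab in enumerate(labels, 1):
        tp += int(lab)
        precision = tp / i
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def fragment_placement_expectation(
    host_len: int,
    seg_src: int,
    seg_len: int,
    read_len: int = 150,
    frag_mean: float = 270.0,
    frag_sd: float = 27.0,
) -> float:
    """Exact probability that a simulated pair has a mate wholly inside the
    planted segment, by enumerating all fragment placements.

    Mirrors the generative model: start uniform on [0, L - read_len];
    fragment length = round(normal) clamped to [read_len, L - start].
    """
    L = host_len
    s = np.arange(0, L - read_len + 1)
    r1_inside = (s >= seg_src) & (s + read_len <= seg_src + seg_len)

    def cdf(t):
        out = norm.cdf(np.asarray(t, dtype=float) + 0.5, frag_mean, frag_sd)
        out = np.where(np.asarray(t) < read_len, 0.0, out)
        out = np.where(np.asarray(t) >= (L - s), 1.0, out)
        return out

    # r2 spans [s + f - read_len, s + f); inside iff f in [a, b]
    a = np.maximum(read_len, seg_src - s + read_len)
    b = seg_src + seg_len - s
    p_r2 = np.clip(cdf(b) - cdf(a - 1), 0.0, 1.0)
    p_r2 = np.where(b >= a, p_r2, 0.0)
    p_pair = np.where(r1_inside, 1.0, p_r2)
    return float(p_pair.mean())
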