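"""Literal, loops-only transcriptions of the score equations.

Deliberately unvectorized and independent of the production code: ranks are
counted by explicit comparison loops so these functions can serve as an
oracle for the rank-within-rank score chain.
"""

import math


def _min_rank_ascending(values, x):
    return 1 + sum(1 for v in values if v < x)


def _min_rank_descending(values, x):
    return 1 + sum(1 for v in values if v > x)


def _window(p, alpha, b):
    w = alpha / b
    l = math.ceil(p / w)
    return min(max(l, 1), b)


def _chain(pairs, alpha, b, fc_threshold):
    """pairs: list of (p, f). Returns combined (pre-rescale) scores."""
    clean = []
    for p, f in pairs:
        p = 1.0 if (p is None or p != p) else p
        f = 0.0 if (f is None or f != f) else f
        clean.append((p, f))
    member_idx = [i for i, (p, _) in enumerate(clean) if p <= alpha]
    out = [0.0] * len(clean)
    n = len(member_idx)
    if n == 0:
        return out
    member_p = [clean[i][0] for i in member_idx]
    score_p = {}
    for i in member_idx:
        p, f = clean[i]
        r = _min_rank_ascending(member_p, p)
        s = (n - r) / n
        if f < fc_threshold:
            s = 0.0
        score_p[i] = s
    windows = {}
    for i in member_idx:
        windows.setdefault(_window(clean[i][0], alpha, b), []).append(i)
    for l, idx in windows.items():
        fs = [clean[i][1] for i in idx]
        ranks = {i: _min_rank_descending(fs, clean[i][1]) for i in idx}
        max_r = max(ranks.values())
        sp = [score_p[i] for i in idx]
        spread = (max(sp) - min(sp)) / len(idx)
        for i in idx:
            score_f = (max_r - ranks[i]) / max_r
            if clean[i][1] < fc_threshold:
                score_f = 0.0
            out[i] = score_p[i] + spread * score_f
    return out


def enrichment_oracle(records, alpha=1.0, b=10, fc_threshold=0.0):
    """records: list of (bait, prey, p, f) -> dict (bait, prey) -> score."""
    combined = _chain([(p, f) for _, _, p, f in records], alpha, b, fc_threshold)
    m = max(combined)
    if m > 0:
        combined = [c / m for c in combined]
    return {(b_, k): c for (b_, k, _, _), c in zip(records, combined)}


def specificity_oracle(records, n_baits, alpha=1.0, b=10, fc_threshold=0.0):
    """records: list of (bait_i, bait_j, prey, p, f) over ordered pairs."""
    combined = _chain([(p, f) for _, _, _, p, f in records], alpha, b, fc_threshold)
    sums = {}
    for (bi, _, k, _, _), c in zip(records, combined):
        sums[(bi, k)] = sums.get((bi, k), 0.0) + c
    avg = {key: v / (n_baits - 1) for key, v in sums.items()}
    m = max(avg.values())
    if m > 0:
        avg = {key: v / m for key, v in avg.items()}
    return avg


def inframe_oracle(records):
    """records: list of (bait, prey, rho with NaN for missing)."""
    defined = [r for _, _, r in records if r == r]
    out = {}
    if defined:
        max_rank = max(_min_rank_ascending(defined, r) for r in defined)
    for bait, prey, rho in records:
        if rho != rho:
            out[(bait, prey)] = 0.0
        else:
            out[(bait, prey)] = _min_rank_ascending(defined, rho) / max_rank
    return out


def _mid_rank(values, x):
    less = sum(1 for v in values if v < x)
    equal = sum(1 for v in values if v == x)
    return less + (equal + 1) / 2.0


def borda_oracle(records, components):
    """records: list of dicts with keys bait, prey and the component scores."""
    out = {}
    baits = sorted({r["bait"] for r in records})
    for bait in baits:
        rows = [r for r in records if r["bait"] == bait]
        mean_ranks = []
        for r in rows:
            ranks = []
            for c in components:
                col = [q[c] for q in rows]
                ranks.append(_mid_rank(col, r[c]))
            mean_ranks.append(sum(ranks) / len(ranks))
        top = max(mean_ranks)
        for r, mr in zip(rows, mean_ranks):
            out[(bait, r["prey"])] = mr / top
    return out
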