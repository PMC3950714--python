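"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by enumeration or direct
counting, sharing nothing with the implementation paths they check except
the published energy-model constants.
"""

from __future__ import annotations

import numpy as np

from nucadapt.fold import (
    HAIRPIN_PENALTY,
    INTERNAL_PENALTY,
    MIN_HAIRPIN,
    MULTI_PENALTY,
    PAIR_STRENGTH,
)


def enumerate_structures(seq: str):
    """Yield every non-crossing pair set obeying the pairing rules."""

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield []
            return
        i = positions[0]
        for rest in rec(positions[1:]):
            yield rest
        for jidx in range(1, len(positions)):
            j = positions[jidx]
            if j - i - 1 >= MIN_HAIRPIN and seq[i] + seq[j] in PAIR_STRENGTH:
                inside = positions[1:jidx]
                outside = positions[jidx + 1 :]
                for ins in rec(inside):
                    for outs in rec(outside):
                        yield [(i, j)] + ins + outs

    yield from rec(tuple(range(len(seq))))


def oracle_structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Loop-decomposition energy computed independently of the engine."""
    if not pairs:
        return 0.0
    pairs = sorted(pairs)

    def direct_children(parent):
        pi, pj = parent
        kids = []
        for p in pairs:
            if p == parent or not (pi < p[0] and p[1] < pj):
                continue
            nested_deeper = any(
                q not in (p, parent)
                and pi < q[0] and q[1] < pj
                and q[0] < p[0] and p[1] < q[1]
                for q in pairs
            )
            if not nested_deeper:
                kids.append(p)
        return kids

    energy = 0.0
    for (i, j) in pairs:
        kids = direct_children((i, j))
        if not kids:
            energy += HAIRPIN_PENALTY
        elif len(kids) == 1:
            k, l1 = kids[0]
            if k == i + 1 and l1 == j - 1:
                energy += -(PAIR_STRENGTH[seq[i] + seq[j]] + PAIR_STRENGTH[seq[k] + seq[l1]]) / 2
            else:
                energy += INTERNAL_PENALTY
        else:
            energy += MULTI_PENALTY
    return energy


def oracle_mfe(seq: str) -> float:
    """Exhaustive-enumeration minimum free energy (lengths <= ~14)."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = oracle_structure_energy(seq, pairs)
        if e < best:
            best = e
    return best


def oracle_welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Textbook unweighted Welch t-test (statistic, df, two-sided p)."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    qa, qb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(qa + qb)
    df = (qa + qb) ** 2 / (qa**2 / (len(a) - 1) + qb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def oracle_one_sample_t(x: np.ndarray, mu0: float) -> tuple[float, float]:
    from scipy import stats

    x = np.asarray(x, float)
    t = (x.mean() - mu0) / np.sqrt(x.var(ddof=1) / len(x))
    p = 2 * stats.t.sf(abs(t), len(x) - 1)
    return float(t), float(p)


def oracle_signed_rank_exact(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by full sign enumeration (n <= 12)."""
    import itertools

    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # midranks for ties
    absd = np.abs(d)
    for v in np.unique(absd):
        m = absd == v
        ranks[m] = ranks[m].mean()
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total
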