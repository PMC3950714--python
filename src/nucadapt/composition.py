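"""Nucleotide, dinucleotide, amino-acid and dipeptide composition statistics.

Frequencies are always ratios of summed counts pooled across the sequences
of one genome (never means of per-gene frequencies), so a genome-level
statistic weights every position equally.

The dinucleotide contrast (DCT) of an ordered pair XpY is

    DCT(XpY) = f(XpY) / (m1(X) * m2(Y))

and equals 1 for position-independent text.  The marginals are the
whole-sequence composition for unrestricted counting and the two positional
compositions for codon-junction contexts (e.g. junction 1-2 uses the
codon-position-1 composition for X and the position-2 composition for Y).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genetics import AA_CLASSES, PURINES

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
CONTEXTS = ("whole", "codon-pos-1", "codon-pos-2", "codon-pos-3")
JUNCTIONS = ("any", "1-2", "2-3", "3-1")
RY_CLASSES = ("RpR", "RpY", "YpR", "YpY")


@dataclass
class CompositionTable:
    """Single-nucleotide frequencies in one positional context."""

    context: str
    freqs: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class DinucTable:
    """Ordered-pair frequencies plus the positional marginals for contrasts."""

    junction: str
    freqs: dict[str, float]
    counts: dict[str, int]
    marginal1: dict[str, float]
    marginal2: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ContrastTable:
    """Dinucleotide contrasts; entries with a zero marginal are absent."""

    junction: str
    contrasts: dict[str, float]
    counts: dict[str, int]


def _norm(counts: Mapping[str, int], keys: Sequence[str]) -> dict[str, float]:
    total = sum(counts.get(k, 0) for k in keys)
    if total == 0:
        return {k: 0.0 for k in keys}
    return {k: counts.get(k, 0) / total for k in keys}


def nuc_composition(seqs: Iterable[str], context: str = "whole") -> CompositionTable:
    """Pooled nucleotide composition, whole-sequence or per codon position."""
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    counts: Counter[str] = Counter()
    n_seqs = 0
    if context == "whole":
        for seq in seqs:
            counts.update(seq)
            n_seqs += 1
    else:
        k = int(context[-1]) - 1  # 0-based offset within codons
        for seq in seqs:
            if len(seq) % 3 != 0:
                raise ValueError("codon-position contexts require CDS input")
            counts.update(seq[k::3])
            n_seqs += 1
    if n_seqs == 0 or sum(counts.values()) == 0:
        raise ValueError("empty input: no nucleotides counted")
    return CompositionTable(
        context=context,
        freqs=_norm(counts, NUCLEOTIDES),
        counts={n: counts.get(n, 0) for n in NUCLEOTIDES},
    )


def combo_load(table: CompositionTable, letters: Iterable[str]) -> float:
    """Summed frequency of a nucleotide combination, e.g. (G+C) at pos 3."""
    letters = list(letters)
    if not letters:
        raise ValueError("letters must be nonempty")
    return sum(table.freqs[letter] for letter in letters)


def gc3(cds_seqs: Iterable[str]) -> float:
    """(G+C)3: G or C fraction at third codon positions."""
    return combo_load(nuc_composition(cds_seqs, "codon-pos-3"), "GC")


def dinuc_frequencies(seqs: Iterable[str], junction: str = "any") -> DinucTable:
    """Ordered dinucleotide frequencies for one junction class.

    ``any`` counts every overlapping adjacent pair within each sequence;
    ``1-2``/``2-3`` count the two within-codon junctions, ``3-1`` the pair
    spanning codon boundaries (the last codon of a gene contributes none).
    Pairs never cross sequence boundaries.
    """
    if junction not in JUNCTIONS:
        raise ValueError(f"junction must be one of {JUNCTIONS}")
    pair_counts: Counter[str] = Counter()
    m1: Counter[str] = Counter()
    m2: Counter[str] = Counter()
    for seq in seqs:
        if len(seq) < 2:
            log.info("skipping length-%d sequence in dinucleotide count", len(seq))
            continue
        if junction == "any":
            firsts, seconds = seq[:-1], seq[1:]
            # marginals: the whole-sequence composition
            m1.update(seq)
            m2.update(seq)
        else:
            if len(seq) % 3 != 0:
                raise ValueError("positional junctions require CDS input")
            if junction == "1-2":
                firsts, seconds = seq[0::3], seq[1::3]
            elif junction == "2-3":
                firsts, seconds = seq[1::3], seq[2::3]
            else:  # 3-1: third base paired with next codon's first base
                firsts, seconds = seq[2:-1:3], seq[3::3]
            # position-specific marginals over all codons of the context
            p1, p2 = (int(junction[0]) - 1, int(junction[2]) - 1)
            m1.update(seq[p1::3])
            m2.update(seq[p2::3])
        pair_counts.update(map("".join, zip(firsts, seconds)))
    return DinucTable(
        junction=junction,
        freqs=_norm(pair_counts, DINUCLEOTIDES),
        counts={d: pair_counts.get(d, 0) for d in DINUCLEOTIDES},
        marginal1=_norm(m1, NUCLEOTIDES),
        marginal2=_norm(m2, NUCLEOTIDES),
    )


def dinucleotide_contrast(dinuc: DinucTable) -> ContrastTable:
    """DCT(XpY) = f(XpY) / (m1(X) * m2(Y)); zero-marginal entries absent."""
    contrasts: dict[str, float] = {}
    for d in DINUCLEOTIDES:
        mx, my = dinuc.marginal1[d[0]], dinuc.marginal2[d[1]]
        if mx > 0 and my > 0:
            contrasts[d] = dinuc.freqs[d] / (mx * my)
        else:
            log.info("DCT(%s) undefined: zero marginal", d)
    return ContrastTable(
        junction=dinuc.junction, contrasts=contrasts, counts=dict(dinuc.counts)
    )


def _ry(symbol: str) -> str:
    return "R" if symbol in PURINES else "Y"


def ry_collapse(dinuc: DinucTable) -> ContrastTable:
    """Purine/pyrimidine (R/Y) contrasts from pooled dinucleotide counts.

    Counts — not contrasts — are pooled by class before re-normalizing and
    re-contrasting, so the result is a genuine 2-letter-alphabet DCT.
    """
    pair_counts: Counter[str] = Counter()
    m1: Counter[str] = Counter()
    m2: Counter[str] = Counter()
    for d, n in dinuc.counts.items():
        pair_counts[f"{_ry(d[0])}p{_ry(d[1])}"] += n
    for nt, f in dinuc.marginal1.items():
        m1[_ry(nt)] += f
    for nt, f in dinuc.marginal2.items():
        m2[_ry(nt)] += f
    total = sum(pair_counts.values())
    contrasts: dict[str, float] = {}
    for cls in RY_CLASSES:
        x, y = cls[0], cls[2]
        if total > 0 and m1[x] > 0 and m2[y] > 0:
            contrasts[cls] = (pair_counts[cls] / total) / (m1[x] * m2[y])
    return ContrastTable(
        junction=dinuc.junction,
        contrasts=contrasts,
        counts={cls: pair_counts[cls] for cls in RY_CLASSES},
    )


def nat_over_null_ratio(nat_value: float, null_value: float) -> float:
    """Plain Nat/NCB (or Nat/Shfld, Nat/dShfld) ratio of a statistic."""
    if null_value == 0:
        raise ZeroDivisionError("null-model value is zero; ratio undefined")
    return nat_value / null_value


# ---------------------------------------------------------------------------
# protein composition


@dataclass
class AAProfile:
    """Pooled amino-acid frequencies plus h/p/c class totals."""

    freqs: dict[str, float]
    class_freqs: dict[str, float]
    counts: dict[str, int]


def aa_profile(proteins: Iterable[str]) -> AAProfile:
    counts: Counter[str] = Counter()
    for p in proteins:
        counts.update(p)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty protein set")
    letters = sorted(set("".join(AA_CLASSES.values())))
    freqs = {a: counts.get(a, 0) / total for a in letters}
    class_freqs = {
        cls: sum(freqs[a] for a in members) for cls, members in AA_CLASSES.items()
    }
    return AAProfile(freqs=freqs, class_freqs=class_freqs,
                     counts={a: counts.get(a, 0) for a in letters})


def dipeptide_contrast(
    proteins: Iterable[str],
) -> tuple[dict[str, float], dict[str, float]]:
    """Dipeptide contrasts f(ab)/(f(a)f(b)) plus the 9 h/p/c class contrasts.

    Marginals come from the same counted positions (first and second members
    of every counted adjacent pair), so i.i.d. text contrasts to 1.
    """
    pair_counts: Counter[str] = Counter()
    m1: Counter[str] = Counter()
    m2: Counter[str] = Counter()
    aa_class = {a: cls for cls, members in AA_CLASSES.items() for a in members}
    for p in proteins:
        if len(p) < 2:
            continue
        pair_counts.update(map("".join, zip(p[:-1], p[1:])))
        m1.update(p[:-1])
        m2.update(p[1:])
    total = sum(pair_counts.values())
    if total == 0:
        raise ValueError("no dipeptides counted (proteins shorter than 2?)")
    f1 = {a: n / total for a, n in m1.items()}
    f2 = {a: n / total for a, n in m2.items()}
    contrasts: dict[str, float] = {}
    for ab, n in pair_counts.items():
        if f1.get(ab[0], 0) > 0 and f2.get(ab[1], 0) > 0:
            contrasts[ab] = (n / total) / (f1[ab[0]] * f2[ab[1]])
    # class-level contrasts from pooled class counts
    cls_pairs: Counter[str] = Counter()
    c1: Counter[str] = Counter()
    c2: Counter[str] = Counter()
    for ab, n in pair_counts.items():
        cls_pairs[aa_class[ab[0]][0] + aa_class[ab[1]][0]] += n
    for a, n in m1.items():
        c1[aa_class[a][0]] += n
    for a, n in m2.items():
        c2[aa_class[a][0]] += n
    class_contrasts: dict[str, float] = {}
    for x in "hpc":
        for y in "hpc":
            if c1[x] > 0 and c2[y] > 0:
                class_contrasts[x + y] = (cls_pairs[x + y] / total) / (
                    (c1[x] / total) * (c2[y] / total)
                )
    return contrasts, class_contrasts
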