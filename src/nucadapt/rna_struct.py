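"""mRNA window folding, stem-pair phase analysis and purine-load metrics.

Coding sequences are transcribed (T -> U) and folded in sliding 50-base
windows.  Every stem base pair is labelled with the codon positions of its
two bases (computed from absolute CDS coordinates, never window-local
ones) and classified into a pairing phase:

* Phase I   — codon positions 1 of the two strands face each other
* Phase II  — codon positions 2 face each other
* Phase III — codon positions 3 face each other

which for a pair of bases at codon positions (p_i, p_j) is determined by
(p_i + p_j) mod 3: residue 2 -> I, 1 -> II, 0 -> III.

Purine-load metrics (A+G fraction, R/Y ratio, ApG frequency, purine-rich
codon classes) are computed separately over loop (unpaired) and stem
(paired) bases, and mRNA-level quantities are reported as ratios to the
same quantity on dicodon-shuffled controls.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .fold import fold_mfe, structure_energy, validate_structure
from .genetics import PURINES

log = logging.getLogger(__name__)

WINDOW_SIZE = 50
DEFAULT_STEP = 10
PHASES = ("I", "II", "III")
_PHASE_BY_RESIDUE = {2: "I", 1: "II", 0: "III"}

#: purine-rich / purine-poor codon classes tracked in loop/stem regions
CODON_CLASSES = ("GGR", "GGY", "AGR", "CGR", "CGY", "GAR", "AAR", "GAY")


def phase_of_pair(pos_i: int, pos_j: int) -> str:
    """Pairing phase of two codon positions (each in {1,2,3})."""
    if pos_i not in (1, 2, 3) or pos_j not in (1, 2, 3):
        raise ValueError("codon positions must be 1, 2 or 3")
    return _PHASE_BY_RESIDUE[(pos_i + pos_j) % 3]


@dataclass
class FoldedWindow:
    """One folded 50-base CDS window with phase-annotated base pairs."""

    gene_id: str
    start: int  # 0-based offset within the CDS
    sequence: str  # RNA alphabet
    structure: str
    energy: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def codon_position(self, idx: int) -> int:
        return (self.start + idx) % 3 + 1

    def pair_phase(self, i: int, j: int) -> str:
        return phase_of_pair(self.codon_position(i), self.codon_position(j))

    def pair_label(self, i: int, j: int) -> str:
        """Label like ``G3•2U``: base and codon position of each partner."""
        return (
            f"{self.sequence[i]}{self.codon_position(i)}"
            f"•{self.codon_position(j)}{self.sequence[j]}"
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def sliding_windows(
    cds: str, window: int = WINDOW_SIZE, step: int = DEFAULT_STEP
) -> list[tuple[int, str]]:
    """(start, subsequence) windows of exact length over one CDS."""
    if len(cds) < window:
        log.info("CDS of length %d shorter than window %d", len(cds), window)
        return []
    return [
        (s, cds[s : s + window]) for s in range(0, len(cds) - window + 1, step)
    ]


def fold_windows(
    cds: str,
    gene_id: str = "",
    window: int = WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    engine: Callable[[str], tuple[str, float]] | None = None,
    max_windows: int | None = None,
) -> list[FoldedWindow]:
    """Fold the sliding windows of one CDS with the given engine."""
    engine = engine or fold_mfe
    out: list[FoldedWindow] = []
    for start, sub in sliding_windows(cds, window, step):
        if max_windows is not None and len(out) >= max_windows:
            break
        rna = sub.replace("T", "U")
        structure, energy = engine(rna)
        pairs = validate_structure(rna, structure)
        out.append(
            FoldedWindow(
                gene_id=gene_id,
                start=start,
                sequence=rna,
                structure=structure,
                energy=energy,
                pairs=pairs,
            )
        )
    return out


def window_from_structure(
    gene_id: str, start: int, sequence: str, structure: str
) -> FoldedWindow:
    """Build a window from a known structure (external or constructed)."""
    rna = sequence.replace("T", "U")
    pairs = validate_structure(rna, structure)
    return FoldedWindow(
        gene_id=gene_id,
        start=start,
        sequence=rna,
        structure=structure,
        energy=structure_energy(rna, pairs) if pairs else 0.0,
        pairs=pairs,
    )


@dataclass
class PhaseSpectrum:
    """Counts of labelled pair kinds per phase."""

    counts: dict[str, Counter]
    totals: dict[str, int]

    @property
    def total_pairs(self) -> int:
        return sum(self.totals.values())

    def extremes(self, phase: str) -> tuple[str, str]:
        """(most frequent, least frequent) pair label of one phase."""
        c = self.counts[phase]
        if not c:
            raise ValueError(f"no pairs observed in phase {phase}")
        ordered = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))
        return ordered[0][0], ordered[-1][0]


def phase_spectrum(windows: Iterable[FoldedWindow]) -> PhaseSpectrum:
    counts: dict[str, Counter] = {ph: Counter() for ph in PHASES}
    for w in windows:
        for i, j in w.pairs:
            counts[w.pair_phase(i, j)][w.pair_label(i, j)] += 1
    totals = {ph: sum(c.values()) for ph, c in counts.items()}
    return PhaseSpectrum(counts=counts, totals=totals)


def stem_loop_annotate(window: FoldedWindow) -> list[str]:
    """Per-base labels: paired -> 'stem', unpaired -> 'loop'.

    Hairpin, bulge, interior and exterior unpaired bases all count as loop.
    """
    labels = ["loop"] * len(window.sequence)
    for i, j in window.pairs:
        labels[i] = labels[j] = "stem"
    return labels


@dataclass
class RegionMetrics:
    """Purine-load metrics of one region (loop or stem) pooled over windows."""

    region: str
    n_bases: int
    ag_fraction: float
    ry_ratio: float | None  # None when the region holds no pyrimidine
    apg_frequency: float
    codon_class_freqs: dict[str, float]


def region_purine_metrics(
    windows: Sequence[FoldedWindow], region: str
) -> RegionMetrics:
    """A+G fraction, R/Y ratio, ApG frequency and codon classes of a region.

    ApG counts only adjacent base pairs whose two bases both carry the
    region label.  A codon (complete within the window, in frame with the
    CDS) is assigned to the region holding the majority (>=2) of its bases.
    """
    if region not in ("loop", "stem"):
        raise ValueError("region must be 'loop' or 'stem'")
    purines = 0
    pyrimidines = 0
    adjacent = 0
    apg = 0
    codon_counts: Counter[str] = Counter()
    codon_total = 0
    for w in windows:
        labels = stem_loop_annotate(w)
        seq = w.sequence
        in_region = [lab == region for lab in labels]
        for idx, flag in enumerate(in_region):
            if not flag:
                continue
            if seq[idx] in PURINES:
                purines += 1
            else:
                pyrimidines += 1
        for idx in range(len(seq) - 1):
            if in_region[idx] and in_region[idx + 1]:
                adjacent += 1
                if seq[idx] == "A" and seq[idx + 1] == "G":
                    apg += 1
        # codons fully inside the window and in frame
        first = (-w.start) % 3
        for c0 in range(first, len(seq) - 2, 3):
            votes = sum(in_region[c0 : c0 + 3])
            if votes >= 2:
                codon = seq[c0 : c0 + 3].replace("U", "T")
                codon_total += 1
                cls = codon[:2] + ("R" if codon[2] in "AG" else "Y")
                if cls in CODON_CLASSES:
                    codon_counts[cls] += 1
    n_bases = purines + pyrimidines
    if n_bases == 0:
        raise ValueError(f"region {region!r} is empty; metrics undefined")
    ry: float | None
    if pyrimidines == 0:
        log.warning("region %s has zero pyrimidines; R/Y undefined", region)
        ry = None
    else:
        ry = purines / pyrimidines
    return RegionMetrics(
        region=region,
        n_bases=n_bases,
        ag_fraction=purines / n_bases,
        ry_ratio=ry,
        apg_frequency=apg / adjacent if adjacent else 0.0,
        codon_class_freqs={
            cls: (codon_counts[cls] / codon_total if codon_total else 0.0)
            for cls in CODON_CLASSES
        },
    )


def energy_summaries(windows: Sequence[FoldedWindow]) -> tuple[float, float | None]:
    """(<E_sg>, <E_bp>): mean window energy and mean energy per base pair.

    Windows without pairs are excluded from <E_bp>; if none has a pair the
    second element is None.
    """
    if not windows:
        raise ValueError("no windows")
    e_sg = sum(w.energy for w in windows) / len(windows)
    per_bp = [w.energy / w.n_pairs for w in windows if w.n_pairs > 0]
    e_bp = sum(per_bp) / len(per_bp) if per_bp else None
    return e_sg, e_bp


def dshfld_normalize(natural: float, control: float) -> float:
    """Ratio of a natural-sequence metric to its dicodon-shuffled control."""
    if control == 0:
        raise ZeroDivisionError("dShfld control metric is zero")
    return natural / control
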