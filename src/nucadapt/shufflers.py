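"""Null-model sequence generators: NCB, Shfld and dShfld.

All three rewrite a coding sequence without touching its protein image:

* ``NCB`` (non-codon-bias) draws each codon uniformly from the synonymous
  family of the encoded amino acid, erasing the genome's codon bias.
* ``Shfld`` redraws each codon from the family weighted by the genome-wide
  codon usage, keeping the bias but destroying 3-1 junction structure
  (in expectation).
* ``dShfld`` (dicodon shuffle) permutes the gene's own codons under the
  constraint that the global dinucleotide count vector is unchanged; it
  keeps protein, per-amino-acid codon multiset (hence positional nucleotide
  composition) and dinucleotide composition, destroying only sequence order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genetics import codon_to_aa, codons_of, synonymous_families, validate_cds
from .genome_io import GenomeDataset

log = logging.getLogger(__name__)

NULL_MODELS = ("ncb", "shfld", "dshfld")


@dataclass
class CodonUsageTable:
    """Relative synonymous-codon frequencies, normalized within families."""

    freqs: dict[str, dict[str, float]]  # aa -> codon -> frequency
    table_id: int = 11

    def __post_init__(self) -> None:
        fams = synonymous_families(self.table_id)
        for aa, fam in fams.items():
            if aa not in self.freqs:
                raise ValueError(f"amino acid {aa} missing from usage table")
            if set(self.freqs[aa]) != set(fam):
                raise ValueError(f"usage table for {aa} does not cover family {fam}")
            total = sum(self.freqs[aa].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"usage for {aa} sums to {total}, expected 1")


def codon_usage(genome: GenomeDataset, table_id: int = 11) -> CodonUsageTable:
    """Genome-wide codon usage pooled over all CDS, normalized per family.

    An amino acid never observed in the genome falls back to a uniform
    distribution over its family (logged) so downstream sampling stays total.
    """
    if not genome.cds:
        raise ValueError("genome has no CDS; codon usage undefined")
    counts: Counter[str] = Counter()
    for cds in genome.cds:
        counts.update(codons_of(cds))
    lookup = codon_to_aa(table_id)
    freqs: dict[str, dict[str, float]] = {}
    for aa, fam in synonymous_families(table_id).items():
        fam_counts = {c: counts.get(c, 0) for c in fam}
        total = sum(fam_counts.values())
        if total == 0:
            log.info("amino acid %s absent from genome %s; uniform fallback",
                     aa, genome.metadata.genome_id)
            freqs[aa] = {c: 1.0 / len(fam) for c in fam}
        else:
            freqs[aa] = {c: n / total for c, n in fam_counts.items()}
    # sanity: every counted codon is a sense codon
    unknown = set(counts) - set(lookup) - {"TAA", "TAG", "TGA"}
    if unknown:
        raise ValueError(f"non-sense codons in CDS set: {sorted(unknown)}")
    return CodonUsageTable(freqs=freqs, table_id=table_id)


def _resample_codons(
    cds: str,
    weights_of: dict[str, tuple[tuple[str, ...], np.ndarray]],
    rng: np.random.Generator,
    table_id: int,
) -> str:
    validate_cds(cds)
    lookup = codon_to_aa(table_id)
    stops = {"TAA", "TAG", "TGA"}
    out: list[str] = []
    for codon in codons_of(cds):
        if codon in stops:
            out.append(codon)  # terminal stop kept verbatim
            continue
        fam, w = weights_of[lookup[codon]]
        out.append(fam[rng.choice(len(fam), p=w)])
    return "".join(out)


def make_ncb(cds: str, rng: np.random.Generator, table_id: int = 11) -> str:
    """Codon-bias-free variant: uniform synonymous codon per site."""
    fams = synonymous_families(table_id)
    weights = {
        aa: (fam, np.full(len(fam), 1.0 / len(fam))) for aa, fam in fams.items()
    }
    return _resample_codons(cds, weights, rng, table_id)


def make_shfld(
    cds: str,
    usage: CodonUsageTable,
    rng: np.random.Generator,
) -> str:
    """Usage-weighted synonymous redraw (codon bias kept, order destroyed)."""
    weights: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for aa, fam in synonymous_families(usage.table_id).items():
        w = np.array([usage.freqs[aa][c] for c in fam], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"usage family for {aa} is all-zero")
        weights[aa] = (fam, w / w.sum())
    return _resample_codons(cds, weights, rng, usage.table_id)


def dinucleotide_counts(seq: str) -> Counter[str]:
    """All overlapping adjacent pairs of one sequence."""
    return Counter(seq[i : i + 2] for i in range(len(seq) - 1))


def make_dshfld(
    cds: str,
    rng: np.random.Generator,
    max_sweeps: int = 30,
    table_id: int = 11,
) -> str:
    """Dicodon-style shuffle via a constrained codon-swap Markov chain.

    Repeatedly proposes swapping the codons at two positions that encode the
    same amino acid and accepts the swap iff the multiset of dinucleotides at
    the (at most four) affected 3-1 junctions is unchanged — which makes the
    global dinucleotide count vector an exact invariant.  Protein sequence
    and the per-amino-acid codon multiset are invariant by construction.

    One sweep is ``len(codons)`` proposals.  If no move is ever accepted the
    input is returned with a low-mobility warning in the log.
    """
    validate_cds(cds)
    lookup = codon_to_aa(table_id)
    stops = {"TAA", "TAG", "TGA"}
    codons = codons_of(cds)
    # positions grouped by amino acid; terminal stop never moves
    by_aa: dict[str, list[int]] = {}
    for idx, codon in enumerate(codons):
        if codon in stops:
            continue
        by_aa.setdefault(lookup[codon], []).append(idx)
    movable = [pos for pos_list in by_aa.values() if len(pos_list) > 1 for pos in pos_list]
    if not movable:
        return cds
    groups = [pos_list for pos_list in by_aa.values() if len(pos_list) > 1]
    group_sizes = np.array([len(g) for g in groups], dtype=float)
    group_p = group_sizes / group_sizes.sum()

    n = len(codons)
    accepted = 0
    n_proposals = max_sweeps * n
    group_idx = rng.choice(len(groups), size=n_proposals, p=group_p)
    u = rng.random((n_proposals, 2))
    for t in range(n_proposals):
        g = groups[group_idx[t]]
        i = g[int(u[t, 0] * len(g))]
        j = g[int(u[t, 1] * len(g))]
        if i == j:
            continue
        ci, cj = codons[i], codons[j]
        if ci == cj:
            continue  # no-op swap, excluded from mobility statistics
        # affected 3-1 junctions: (i-1,i), (i,i+1), (j-1,j), (j,j+1)
        before: list[str] = []
        after: list[str] = []
        for pos, old, new in ((i, ci, cj), (j, cj, ci)):
            if pos > 0:
                left = codons[pos - 1]
                left_new = left
                # neighbour may itself be the other swapped position
                if pos - 1 == i:
                    left_new = cj
                elif pos - 1 == j:
                    left_new = ci
                before.append(left[2] + old[0])
                after.append(left_new[2] + new[0])
            if pos < n - 1:
                right = codons[pos + 1]
                right_new = right
                if pos + 1 == i:
                    right_new = cj
                elif pos + 1 == j:
                    right_new = ci
                before.append(old[2] + right[0])
                after.append(new[2] + right_new[0])
        if Counter(before) == Counter(after):
            codons[i], codons[j] = cj, ci
            accepted += 1
    if accepted == 0:
        log.info("dshfld: no accepted swap in %d sweeps (low mobility)", max_sweeps)
        return cds
    return "".join(codons)


def apply_null_model(
    genome: GenomeDataset,
    model: str,
    rng: np.random.Generator,
    max_sweeps: int = 30,
    table_id: int = 11,
) -> list[str]:
    """Null-model variants of every CDS of one genome (gene-wise)."""
    if model not in NULL_MODELS:
        raise ValueError(f"model must be one of {NULL_MODELS}")
    if model == "ncb":
        return [make_ncb(c, rng, table_id) for c in genome.cds]
    if model == "shfld":
        usage = codon_usage(genome, table_id)
        return [make_shfld(c, usage, rng) for c in genome.cds]
    return [make_dshfld(c, rng, max_sweeps, table_id) for c in genome.cds]
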