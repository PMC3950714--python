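"""Genetic-code helpers shared by the ingestion and null-model layers.

The prokaryotic (bacterial/archaeal) code, NCBI translation table 11, is the
default; any table id known to Biopython can be requested instead.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

DNA_ALPHABET = frozenset("ACGT")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: hydrophobic / polar / charged partition of the 20 amino acids
AA_CLASSES: dict[str, str] = {
    "charged": "DEKR",
    "hydrophobic": "CFILMPVW",
    "polar": "AGHNQSTY",
}

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


class MalformedCDSError(ValueError):
    """CDS length is not a multiple of three."""


class AlphabetError(ValueError):
    """Sequence contains symbols outside {A,C,G,T}."""


class InternalStopError(ValueError):
    """CDS contains an in-frame stop codon before its final codon."""


@lru_cache(maxsize=None)
def codon_to_aa(table_id: int = 11) -> dict[str, str]:
    """Map every sense codon to its amino-acid letter for a code table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table)


@lru_cache(maxsize=None)
def stop_codons(table_id: int = 11) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


@lru_cache(maxsize=None)
def synonymous_families(table_id: int = 11) -> dict[str, tuple[str, ...]]:
    """Amino acid -> sorted tuple of its synonymous codons."""
    fams: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa(table_id).items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in fams.items()}


def codons_of(cds: str) -> list[str]:
    """Split a validated CDS into its codons."""
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def validate_cds(cds: str) -> None:
    if len(cds) % 3 != 0:
        raise MalformedCDSError(
            f"CDS length {len(cds)} is not a multiple of 3"
        )
    bad = set(cds) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-ACGT symbols in CDS: {sorted(bad)}")


def translate_cds(
    cds: str,
    table_id: int = 11,
    internal_stop: str = "reject",
) -> str:
    """Translate a coding sequence codon by codon.

    A trailing stop codon is allowed and dropped.  In-frame internal stops
    are rejected by default; ``internal_stop='truncate'`` cuts the protein
    at the first stop instead.
    """
    validate_cds(cds)
    lookup = codon_to_aa(table_id)
    stops = stop_codons(table_id)
    aas: list[str] = []
    codons = codons_of(cds)
    for k, codon in enumerate(codons):
        if codon in stops:
            if k == len(codons) - 1:
                break
            if internal_stop == "truncate":
                break
            raise InternalStopError(
                f"internal stop codon {codon} at codon index {k}"
            )
        aas.append(lookup[codon])
    return "".join(aas)
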