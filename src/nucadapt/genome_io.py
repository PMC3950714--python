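"""Genome ingestion: sequence partitions, metadata, thermal groups, cohorts.

One genome is a :class:`GenomeDataset` — its coding sequences plus the
non-coding, tRNA and rRNA partitions, and a :class:`GenomeMetadata` record
carrying the domain of life, optimal growth temperature (OGT, degC) and
oxygen-tolerance class used to define comparison groups.

Sequence classes arrive as multi-record FASTA files whose record ids are
namespaced ``genome_id|class|gene_id``; metadata is one TSV row per genome.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .genetics import (
    DNA_ALPHABET,
    InternalStopError,
    translate_cds,
    validate_cds,
)

log = logging.getLogger(__name__)

DOMAINS = ("Archaea", "Bacteria")
OXYGEN_CLASSES = ("aerobic", "anaerobic", "facultative", "microaerophilic", "unknown")
SEQUENCE_CLASSES = ("cds", "ncdna", "trna", "rrna")

#: left-closed OGT thresholds separating the four thermal groups (degC)
THERMAL_BOUNDS = (24.0, 50.0, 80.0)
THERMAL_LABELS = ("psychrophile", "mesophile", "thermophile", "hyperthermophile")

#: OGTs excluded from correlation cohorts (parasite/symbiont-dominated bins)
CORRELATION_EXCLUDED_OGTS = frozenset({26.0, 30.0, 37.0})


class UnclassifiableError(ValueError):
    """Genome cannot be assigned to a thermal group (no OGT)."""


class CohortEmptyWarning(UserWarning):
    """A cohort builder produced an empty cohort."""


@dataclass(frozen=True)
class GenomeMetadata:
    """Per-genome annotation used for grouping and correlation."""

    genome_id: str
    domain: str
    ogt: float | None = None
    oxygen: str = "unknown"
    genome_size: int = 0

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if self.oxygen not in OXYGEN_CLASSES:
            raise ValueError(
                f"oxygen must be one of {OXYGEN_CLASSES}, got {self.oxygen!r}"
            )
        if self.ogt is not None and not (0.0 <= self.ogt <= 130.0):
            raise ValueError(f"OGT {self.ogt} outside [0, 130] degC")
        if self.genome_size < 0:
            raise ValueError("genome_size must be positive")


@dataclass
class GenomeDataset:
    """One genome's partitioned sequences plus metadata."""

    metadata: GenomeMetadata
    cds: list[str] = field(default_factory=list)
    ncdna: list[str] = field(default_factory=list)
    trna: list[str] = field(default_factory=list)
    rrna: list[str] = field(default_factory=list)
    cds_ids: list[str] = field(default_factory=list)

    def sequences(self, seq_class: str) -> list[str]:
        if seq_class not in SEQUENCE_CLASSES:
            raise ValueError(f"unknown sequence class {seq_class!r}")
        return getattr(self, seq_class)

    def proteins(self, table_id: int = 11) -> list[str]:
        return [translate_cds(c, table_id=table_id) for c in self.cds]

    @property
    def total_length(self) -> int:
        return sum(
            len(s) for cls in SEQUENCE_CLASSES for s in getattr(self, cls)
        )


def classify_thermal_group(ogt: float | None) -> str:
    """Thermal group from OGT with left-closed bounds at 24, 50, 80 degC."""
    if ogt is None:
        raise UnclassifiableError("OGT absent; thermal group undefined")
    for bound, label in zip(THERMAL_BOUNDS, THERMAL_LABELS):
        if ogt < bound:
            return label
    return THERMAL_LABELS[-1]


def build_correlation_cohort(genomes: Sequence[GenomeDataset]) -> list[GenomeDataset]:
    """Drop genomes whose OGT is exactly 26, 30 or 37 degC, keeping order.

    Those OGT bins are dominated by parasites and symbionts whose
    composition does not track temperature, so they are excluded from every
    OGT correlation.
    """
    kept = [
        g
        for g in genomes
        if g.metadata.ogt is not None
        and float(g.metadata.ogt) not in CORRELATION_EXCLUDED_OGTS
    ]
    if genomes and not kept:
        warnings.warn("correlation cohort is empty", CohortEmptyWarning, stacklevel=2)
    return kept


def build_oxygen_cohorts(
    genomes: Sequence[GenomeDataset],
) -> tuple[list[GenomeDataset], list[GenomeDataset]]:
    """Partition into (aerobic, anaerobic); all other classes join neither."""
    aerobes = [g for g in genomes if g.metadata.oxygen == "aerobic"]
    anaerobes = [g for g in genomes if g.metadata.oxygen == "anaerobic"]
    return aerobes, anaerobes


# ---------------------------------------------------------------------------
# file formats


def read_metadata(path: str | Path) -> dict[str, GenomeMetadata]:
    """Read the metadata TSV (genome_id/domain/ogt/oxygen[/genome_size])."""
    df = pd.read_csv(
        path, sep="\t", dtype={"genome_id": str}, float_precision="round_trip"
    )
    required = {"genome_id", "domain", "ogt", "oxygen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    out: dict[str, GenomeMetadata] = {}
    for row in df.itertuples(index=False):
        ogt = None if pd.isna(row.ogt) else float(row.ogt)
        size = int(getattr(row, "genome_size", 0) or 0)
        out[row.genome_id] = GenomeMetadata(
            genome_id=row.genome_id,
            domain=row.domain,
            ogt=ogt,
            oxygen=row.oxygen,
            genome_size=size,
        )
    return out


def write_metadata(metas: Iterable[GenomeMetadata], path: str | Path) -> None:
    rows = [
        {
            "genome_id": m.genome_id,
            "domain": m.domain,
            "ogt": "" if m.ogt is None else m.ogt,
            "oxygen": m.oxygen,
            "genome_size": m.genome_size,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _clean_sequences(
    records: Iterable[tuple[str, str]],
    seq_class: str,
    internal_stop: str = "reject",
) -> tuple[list[str], list[str], int]:
    """Validate records of one class; drop those with ambiguity codes.

    Returns (sequences, ids, n_dropped).  For CDS, records failing frame or
    internal-stop validation are dropped (counted) rather than fatal, since
    real annotation sets routinely contain a few pseudogene fragments.
    """
    seqs: list[str] = []
    ids: list[str] = []
    dropped = 0
    for rec_id, seq in records:
        seq = seq.upper().replace("U", "T")
        if set(seq) - DNA_ALPHABET:
            dropped += 1
            continue
        if seq_class == "cds":
            try:
                validate_cds(seq)
                translate_cds(seq, internal_stop=internal_stop)
            except (ValueError, InternalStopError):
                dropped += 1
                continue
        seqs.append(seq)
        ids.append(rec_id)
    if dropped:
        log.info("dropped %d invalid %s records", dropped, seq_class)
    return seqs, ids, dropped


def load_genomes(
    fasta_dir: str | Path,
    metadata_path: str | Path,
    internal_stop: str = "reject",
) -> list[GenomeDataset]:
    """Load a genome collection from a FASTA directory plus metadata TSV.

    Each sequence class is read from ``<fasta_dir>/<class>.fasta`` with
    record ids ``genome_id|class|gene_id``; classes missing on disk are
    treated as empty.
    """
    fasta_dir = Path(fasta_dir)
    metas = read_metadata(metadata_path)
    by_genome: dict[str, dict[str, list[tuple[str, str]]]] = {
        gid: {cls: [] for cls in SEQUENCE_CLASSES} for gid in metas
    }
    for cls in SEQUENCE_CLASSES:
        path = fasta_dir / f"{cls}.fasta"
        if not path.exists():
            continue
        for rec in SeqIO.parse(str(path), "fasta"):
            gid = rec.id.split("|", 1)[0]
            if gid in by_genome:
                by_genome[gid][cls].append((rec.id, str(rec.seq)))
    genomes: list[GenomeDataset] = []
    for gid, meta in metas.items():
        parts: dict[str, list[str]] = {}
        cds_ids: list[str] = []
        for cls in SEQUENCE_CLASSES:
            seqs, ids, _ = _clean_sequences(
                by_genome[gid][cls], cls, internal_stop=internal_stop
            )
            parts[cls] = seqs
            if cls == "cds":
                cds_ids = ids
        g = GenomeDataset(metadata=meta, cds_ids=cds_ids, **parts)
        if meta.genome_size == 0:
            g.metadata = GenomeMetadata(
                genome_id=meta.genome_id,
                domain=meta.domain,
                ogt=meta.ogt,
                oxygen=meta.oxygen,
                genome_size=g.total_length,
            )
        genomes.append(g)
    return genomes


def write_genomes_fasta(genomes: Sequence[GenomeDataset], out_dir: str | Path) -> None:
    """Write a collection back to the class-per-file FASTA layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cls in SEQUENCE_CLASSES:
        lines: list[str] = []
        for g in genomes:
            for k, seq in enumerate(g.sequences(cls)):
                if cls == "cds" and k < len(g.cds_ids):
                    rid = g.cds_ids[k]
                else:
                    rid = f"{g.metadata.genome_id}|{cls}|{cls}_{k:05d}"
                lines.append(f">{rid}\n{seq}")
        (out_dir / f"{cls}.fasta").write_text("\n".join(lines) + "\n")


DATASET_FORMAT_VERSION = 1


def write_dataset_jsonl(genomes: Sequence[GenomeDataset], path: str | Path) -> None:
    """Serialize a collection as JSON lines (one genome per line, versioned)."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"format": "nucadapt-dataset", "version": DATASET_FORMAT_VERSION}) + "\n")
        for g in genomes:
            m = g.metadata
            fh.write(
                json.dumps(
                    {
                        "genome_id": m.genome_id,
                        "domain": m.domain,
                        "ogt": m.ogt,
                        "oxygen": m.oxygen,
                        "genome_size": m.genome_size,
                        "cds": g.cds,
                        "cds_ids": g.cds_ids,
                        "ncdna": g.ncdna,
                        "trna": g.trna,
                        "rrna": g.rrna,
                    }
                )
                + "\n"
            )


def read_dataset_jsonl(path: str | Path) -> list[GenomeDataset]:
    genomes: list[GenomeDataset] = []
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "nucadapt-dataset":
            raise ValueError("not a nucadapt dataset file")
        if header.get("version") != DATASET_FORMAT_VERSION:
            raise ValueError(f"unsupported dataset version {header.get('version')}")
        for line in fh:
            d = json.loads(line)
            genomes.append(
                GenomeDataset(
                    metadata=GenomeMetadata(
                        genome_id=d["genome_id"],
                        domain=d["domain"],
                        ogt=d["ogt"],
                        oxygen=d["oxygen"],
                        genome_size=d["genome_size"],
                    ),
                    cds=d["cds"],
                    cds_ids=d.get("cds_ids", []),
                    ncdna=d["ncdna"],
                    trna=d["trna"],
                    rrna=d["rrna"],
                )
            )
    return genomes
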