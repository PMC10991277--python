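"""Corpus construction: genomes, proteins and temperature-class labelling.

A corpus ties every protein to its source genome and stamps the genome's
optimal growth temperature (OGT, °C) onto the protein as the regression
target.  Genomes are classed as psychrophilic (OGT < 20 °C), mesophilic
(30 < OGT < 40 °C) or thermophilic (OGT > 50 °C); the boundaries and the
gaps [20, 30] and [40, 50] are excluded from labelling.  Proteins of
excluded genomes are retained unlabelled so they can still be scored by a
trained model (e.g. during mining).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: 20 standard residues, alphabetical single-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: single symbol every non-standard residue is normalised to.
UNKNOWN_AA = "X"

_NON_STANDARD = re.compile(f"[^{STANDARD_AA}]")


class TempClass(str, Enum):
    """Thermal lifestyle class of a genome, derived from its OGT."""

    PSYCHROPHILIC = "psychrophilic"
    MESOPHILIC = "mesophilic"
    THERMOPHILIC = "thermophilic"
    EXCLUDED = "excluded"


def assign_temperature_class(ogt_celsius: float) -> TempClass:
    """Map an optimal growth temperature to its class.

    Strict inequalities: psychrophilic iff OGT < 20, mesophilic iff
    30 < OGT < 40, thermophilic iff OGT > 50.  Boundary values and the
    gaps [20, 30] and [40, 50] map to ``TempClass.EXCLUDED``.

    Raises
    ------
    ValueError
        If ``ogt_celsius`` is NaN or infinite (invalid metadata).
    """
    ogt = float(ogt_celsius)
    if not math.isfinite(ogt):
        raise ValueError(f"OGT must be finite, got {ogt_celsius!r}")
    if ogt < 20.0:
        return TempClass.PSYCHROPHILIC
    if 30.0 < ogt < 40.0:
        return TempClass.MESOPHILIC
    if ogt > 50.0:
        return TempClass.THERMOPHILIC
    return TempClass.EXCLUDED


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    species: str
    ogt_celsius: float
    temp_class: TempClass

    @classmethod
    def from_metadata(cls, genome_id: str, species: str, ogt_celsius: float) -> "GenomeRecord":
        return cls(
            genome_id=str(genome_id),
            species=str(species),
            ogt_celsius=float(ogt_celsius),
            temp_class=assign_temperature_class(ogt_celsius),
        )


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    sequence: str
    label_celsius: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")


@dataclass
class Corpus:
    """Genomes plus proteins with referential integrity between them."""

    genomes: dict[str, GenomeRecord] = field(default_factory=dict)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def genome_of(self, protein_id: str) -> GenomeRecord:
        return self.genomes[self.proteins[protein_id].genome_id]

    def labelled_proteins(self) -> list[ProteinRecord]:
        return [p for p in self.proteins.values() if p.label_celsius is not None]

    def labelled_protein_ids(self) -> set[str]:
        return {p.protein_id for p in self.proteins.values() if p.label_celsius is not None}

    def add_genome(self, genome: GenomeRecord) -> None:
        if genome.genome_id in self.genomes:
            raise ValueError(f"duplicate genome_id {genome.genome_id!r}")
        self.genomes[genome.genome_id] = genome

    def add_protein(self, protein: ProteinRecord) -> None:
        if protein.protein_id in self.proteins:
            raise ValueError(f"duplicate protein_id {protein.protein_id!r}")
        if protein.genome_id not in self.genomes:
            raise KeyError(
                f"protein {protein.protein_id!r} references unknown genome "
                f"{protein.genome_id!r}"
            )
        if protein.label_celsius is not None:
            ogt = self.genomes[protein.genome_id].ogt_celsius
            if protein.label_celsius != ogt:
                raise ValueError(
                    f"label of {protein.protein_id!r} ({protein.label_celsius}) "
                    f"differs from genome OGT ({ogt})"
                )
        self.proteins[protein.protein_id] = protein


def normalise_sequence(sequence: str) -> str:
    """Uppercase and collapse non-standard residues (B, J, O, U, Z, X, *, …)
    onto the single unknown symbol so downstream encoding sees a closed
    21-letter alphabet."""
    return _NON_STANDARD.sub(UNKNOWN_AA, sequence.upper())


def default_genome_id(record_id: str) -> str:
    """Default FASTA-record → genome mapping: text before the first ``|``."""
    return record_id.split("|", 1)[0]


def load_metadata(metadata_path: str | Path) -> list[GenomeRecord]:
    """Read the genome metadata table (TSV with header row).

    Required columns: ``genome_id``, ``species``, ``ogt_celsius``.
    """
    table = pd.read_csv(metadata_path, sep="\t", dtype={"genome_id": str})
    missing = {"genome_id", "species", "ogt_celsius"} - set(table.columns)
    if missing:
        raise ValueError(f"metadata {metadata_path} lacks columns: {sorted(missing)}")
    return [
        GenomeRecord.from_metadata(row.genome_id, row.species, row.ogt_celsius)
        for row in table.itertuples()
    ]


def load_corpus(
    fasta_paths: Sequence[str | Path],
    metadata_path: str | Path,
    genome_id_map: Mapping[str, str] | None = None,
) -> Corpus:
    """Build a :class:`Corpus` from protein FASTA files and a metadata table.

    Every genome gets a temperature class; proteins of non-excluded genomes
    are stamped with the genome OGT as ``label_celsius``, proteins of
    excluded genomes stay unlabelled.  ``genome_id_map`` overrides the
    default record-id → genome-id rule (prefix before the first ``|``).

    Raises
    ------
    ValueError
        On an empty FASTA file or a record whose genome is not in the
        metadata (the error names the offending records).
    """
    corpus = Corpus()
    for genome in load_metadata(metadata_path):
        corpus.add_genome(genome)
    corpus.provenance.append(f"metadata: {metadata_path}")

    orphans: list[str] = []
    n_normalised = 0
    for path in fasta_paths:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"FASTA file {path} contains no records")
        for rec in records:
            gid = (
                genome_id_map[rec.id]
                if genome_id_map is not None
                else default_genome_id(rec.id)
            )
            if gid not in corpus.genomes:
                orphans.append(rec.id)
                continue
            raw = str(rec.seq)
            seq = normalise_sequence(raw)
            if seq != raw:
                n_normalised += 1
                logger.debug("normalised non-standard residues in %s", rec.id)
            genome = corpus.genomes[gid]
            label = None if genome.temp_class is TempClass.EXCLUDED else genome.ogt_celsius
            corpus.add_protein(
                ProteinRecord(
                    protein_id=rec.id, genome_id=gid, sequence=seq, label_celsius=label
                )
            )
        corpus.provenance.append(f"fasta: {path}")
    if orphans:
        raise ValueError(
            "FASTA records reference genomes absent from metadata: "
            + ", ".join(sorted(orphans))
        )
    if n_normalised:
        logger.info("normalised non-standard residues in %d records", n_normalised)
    return corpus


def corpus_summary(corpus: Corpus) -> pd.DataFrame:
    """Per-class genome and labelled-protein counts (zero classes included),
    plus an ``unlabelled`` protein row covering excluded genomes."""
    classes = [TempClass.PSYCHROPHILIC, TempClass.MESOPHILIC, TempClass.THERMOPHILIC]
    rows = []
    for cls in classes:
        gids = {g.genome_id for g in corpus.genomes.values() if g.temp_class is cls}
        n_prot = sum(
            1
            for p in corpus.proteins.values()
            if p.genome_id in gids and p.label_celsius is not None
        )
        rows.append({"temp_class": cls.value, "n_genomes": len(gids), "n_proteins": n_prot})
    n_unlabelled = sum(1 for p in corpus.proteins.values() if p.label_celsius is None)
    n_excluded_genomes = sum(
        1 for g in corpus.genomes.values() if g.temp_class is TempClass.EXCLUDED
    )
    rows.append(
        {
            "temp_class": "unlabelled",
            "n_genomes": n_excluded_genomes,
            "n_proteins": n_unlabelled,
        }
    )
    return pd.DataFrame(rows, columns=["temp_class", "n_genomes", "n_proteins"])


def write_summary(summary: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    summary.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary.to_json(json_path, orient="records", indent=2)


def proteins_of(corpus: Corpus, protein_ids: Iterable[str]) -> list[ProteinRecord]:
    """Resolve ids to records, erroring with the full list of misses."""
    missing = [pid for pid in protein_ids if pid not in corpus.proteins]
    if missing:
        raise KeyError(f"unknown protein ids: {', '.join(sorted(missing)[:20])}")
    return [corpus.proteins[pid] for pid in protein_ids]
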