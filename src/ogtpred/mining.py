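"""Mining thermophilic enzyme candidates from metagenome protein sets.

The contract starts at a precomputed HMMER3 ``hmmsearch --tblout`` file
(e.g. a Pfam chitinase domain such as PF00704 searched against a
metagenome gene catalogue): hits are parsed, deduplicated and filtered by
full-sequence E-value, their sequences scored with a trained temperature
regressor, ranked by predicted optimal temperature, and binned into
psychrophilic / mesophilic / thermophilic classes for reporting.  The
top-ranked candidates can be exported as FASTA plus a ranked TSV for
downstream synthesis and wet-lab validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ogtpred.corpus import Corpus, ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DomainHit",
    "MiningResult",
    "parse_hmmsearch_tblout",
    "filter_hits",
    "mine",
    "export_candidates",
]

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_THRESHOLDS = (20.0, 50.0)

#: minimum whitespace-separated fields on a tblout data line (18 fixed
#: columns before the free-text description).
_TBLOUT_MIN_FIELDS = 18


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    pfam_id: str
    full_seq_evalue: float
    full_seq_score: float

    def __post_init__(self) -> None:
        if self.full_seq_evalue < 0:
            raise ValueError(
                f"negative E-value {self.full_seq_evalue} for {self.protein_id!r}"
            )


def parse_hmmsearch_tblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-target table (``hmmsearch --tblout``).

    One hit per data line; ``#`` comment lines are ignored.  The target
    name becomes ``protein_id`` and the query accession (falling back to
    the query name when the accession is ``-``) becomes ``pfam_id``.
    Full-sequence E-value (column 5) and bit score (column 6) are kept.

    Raises ``ValueError`` with the line number on malformed data lines; an
    empty file yields an empty list with a logged warning.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < _TBLOUT_MIN_FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_TBLOUT_MIN_FIELDS} fields, "
                    f"got {len(fields)}"
                )
            target_name, _target_acc, query_name, query_acc = fields[:4]
            try:
                evalue = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparsable E-value/score fields "
                    f"{fields[4]!r}, {fields[5]!r}"
                ) from exc
            pfam_id = query_acc if query_acc != "-" else query_name
            hits.append(
                DomainHit(
                    protein_id=target_name,
                    pfam_id=pfam_id,
                    full_seq_evalue=evalue,
                    full_seq_score=score,
                )
            )
    if not hits:
        logger.warning("tblout file %s contains no data lines", path)
    return hits


def filter_hits(hits: Iterable[DomainHit], evalue_max: float = DEFAULT_EVALUE_MAX) -> list[DomainHit]:
    """Keep hits with full-sequence E-value ≤ ``evalue_max``, one row per
    protein (best E-value wins; bit score breaks E-value ties).

    Output is sorted by (E-value, protein_id) for determinism.
    """
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be > 0, got {evalue_max}")
    best: dict[str, DomainHit] = {}
    for hit in hits:
        cur = best.get(hit.protein_id)
        if (
            cur is None
            or hit.full_seq_evalue < cur.full_seq_evalue
            or (hit.full_seq_evalue == cur.full_seq_evalue and hit.full_seq_score > cur.full_seq_score)
        ):
            best[hit.protein_id] = hit
    kept = [h for h in best.values() if h.full_seq_evalue <= evalue_max]
    return sorted(kept, key=lambda h: (h.full_seq_evalue, h.protein_id))


@dataclass
class MiningResult:
    """Ranked, temperature-annotated candidate list.

    ``ranked`` columns: rank, protein_id, predicted_temp, temp_bin,
    full_seq_evalue — sorted by predicted temperature descending (rank 1
    is the hottest), ties broken by ascending protein_id.
    ``bin_fractions`` sum to 1 over psychrophilic/mesophilic/thermophilic.
    """

    ranked: pd.DataFrame
    bin_fractions: dict[str, float]
    thresholds_used: tuple[float, float]


def _resolve_sequences(
    source: Corpus | Mapping[str, str], protein_ids: Sequence[str]
) -> list[ProteinRecord]:
    if isinstance(source, Corpus):
        lookup: Mapping[str, str] = {
            pid: source.proteins[pid].sequence for pid in source.proteins
        }
    else:
        lookup = source
    missing = sorted(pid for pid in protein_ids if pid not in lookup)
    if missing:
        raise KeyError(
            "hits reference sequences absent from the source: "
            + ", ".join(missing[:20])
        )
    return [
        ProteinRecord(protein_id=pid, genome_id="", sequence=lookup[pid])
        for pid in protein_ids
    ]


def mine(
    hits: Sequence[DomainHit],
    sequence_source: Corpus | Mapping[str, str],
    model,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> MiningResult:
    """Predict temperatures for all hit proteins, rank and bin them.

    Binning: predicted < t_low → psychrophilic, > t_high → thermophilic,
    otherwise mesophilic (exhaustive and exclusive for any t_low < t_high).
    ``model`` is any object with ``predict(list[ProteinRecord]) -> array``.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError(f"thresholds must satisfy t_low < t_high, got {thresholds}")
    if len(hits) == 0:
        raise ValueError("no hits to mine")
    ids = [h.protein_id for h in hits]
    proteins = _resolve_sequences(sequence_source, ids)
    preds = np.asarray(model.predict(proteins), dtype=np.float64)
    table = pd.DataFrame(
        {
            "protein_id": ids,
            "predicted_temp": preds,
            "full_seq_evalue": [h.full_seq_evalue for h in hits],
        }
    )
    table["temp_bin"] = np.where(
        table["predicted_temp"] < t_low,
        "psychrophilic",
        np.where(table["predicted_temp"] > t_high, "thermophilic", "mesophilic"),
    )
    table = table.sort_values(
        ["predicted_temp", "protein_id"], ascending=[False, True], ignore_index=True
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    n = len(table)
    fractions = {
        bin_name: float((table["temp_bin"] == bin_name).sum()) / n
        for bin_name in ("psychrophilic", "mesophilic", "thermophilic")
    }
    return MiningResult(
        ranked=table[
            ["rank", "protein_id", "predicted_temp", "temp_bin", "full_seq_evalue"]
        ],
        bin_fractions=fractions,
        thresholds_used=(float(t_low), float(t_high)),
    )


def export_candidates(
    result: MiningResult,
    top_n: int,
    sequence_source: Corpus | Mapping[str, str],
    fasta_path: str | Path,
    tsv_path: str | Path,
) -> pd.DataFrame:
    """Write the top ``top_n`` candidates as FASTA (rank and predicted
    temperature in the description) and the matching ranked TSV.

    Asking for more candidates than exist exports everything with a
    warning.  Returns the exported table.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    table = result.ranked
    if top_n > len(table):
        logger.warning(
            "top_n=%d exceeds table size %d; exporting all", top_n, len(table)
        )
        top_n = len(table)
    head = table.head(top_n)
    proteins = _resolve_sequences(sequence_source, list(head["protein_id"]))
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.protein_id,
            description=f"rank={int(row.rank)} predicted_temp={row.predicted_temp:.2f}C bin={row.temp_bin}",
        )
        for p, row in zip(proteins, head.itertuples())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    head.to_csv(tsv_path, sep="\t", index=False)
    return head
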