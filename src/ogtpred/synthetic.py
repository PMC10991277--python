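"""Desk-scale synthetic corpora with a planted composition–temperature
signal.

The generator emulates the statistical skeleton of an OGT-labelled corpus:
genomes drawn from three temperature classes (OGT uniform in (5, 19),
(31, 39) and (51, 95) °C, so the excluded bands [20, 30] and [40, 50] are
never populated), proteins whose amino-acid composition is tilted linearly
with genome OGT — hot-enriched residues E, L, V, Y up, cold-enriched
D, H, M, Q, S, T down — and cross-genome ortholog families built by
copying an ancestor sequence into member genomes with ~10% per-site
substitution.  Substitutions are composition-targeted, as in long-term
compositional adaptation of real homologs: substituted sites
preferentially convert residues the member genome's tilted background
has in surplus into residues it has in deficit, so each member's overall
composition tracks its own genome's OGT while the family stays highly
sequence-identical.  Matching FASTA /
metadata-TSV / Orthogroups.tsv / hmmsearch-tblout fixtures can be written
so every pipeline stage is testable without downloads.

The signal is composition-only (no positional motif): a small CNN can
learn it quickly on one CPU, and exact per-protein ground truth is
returned for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ogtpred.corpus import (
    STANDARD_AA,
    Corpus,
    GenomeRecord,
    ProteinRecord,
)
from ogtpred.orthology import OrthologCluster

__all__ = [
    "SyntheticSpec",
    "generate_corpus",
    "generate_mining_fixture",
    "write_corpus_files",
    "composition_weights",
]

_AA_ARRAY = np.array(list(STANDARD_AA))
_CLASS_BANDS = {
    "psy": (5.0, 19.0),
    "mes": (31.0, 39.0),
    "thr": (51.0, 95.0),
}
#: midpoint and half-range of the overall OGT span, for the linear tilt
_T_MID, _T_HALF = 50.0, 45.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``enrichment_strength`` scales the linear composition tilt (0 = no
    signal, 1 = maximal); ``label_noise_sd`` jitters the temperature at
    which a protein's composition is drawn (the label itself stays the
    genome OGT); ``family_effect_sd`` is the standard deviation of a
    per-family compositional baseline shift shared by all members of an
    ortholog family (the analogue of function-driven composition that
    confounds temperature prediction and motivates cluster-level
    splitting; unclustered proteins draw their own one-protein effect);
    ``substitution_rate`` is the per-site probability that a
    family member substitutes the ancestor residue, with substitutions
    targeted at converting residues the member's tilted background has in
    surplus into residues it has in deficit.
    """

    n_genomes_per_class: int = 6
    proteins_per_genome: int = 200
    families: int = 600
    family_span: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.2}
    )
    length_range: tuple[int, int] = (150, 220)
    hot_enriched: frozenset[str] = frozenset("ELVY")
    cold_enriched: frozenset[str] = frozenset("DHMQST")
    enrichment_strength: float = 0.8
    label_noise_sd: float = 3.0
    substitution_rate: float = 0.1
    family_effect_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hot_enriched & self.cold_enriched:
            raise ValueError("hot_enriched and cold_enriched must be disjoint")
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise ValueError(
                f"enrichment_strength must be in [0, 1], got {self.enrichment_strength}"
            )
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError(
                f"substitution_rate must be in [0, 1], got {self.substitution_rate}"
            )
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length_range {self.length_range}")
        spans = sorted(self.family_span)
        if not spans or min(spans) < 2:
            raise ValueError("family_span must cover spans >= 2")
        if max(spans) > 3 * self.n_genomes_per_class:
            raise ValueError(
                f"family span {max(spans)} exceeds genome count "
                f"{3 * self.n_genomes_per_class}"
            )
        total = sum(self.family_span.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"family_span probabilities sum to {total}, not 1")


def composition_weights(
    ogt_celsius: float, spec: SyntheticSpec
) -> np.ndarray:
    """Residue sampling distribution for a protein drawn at temperature
    ``ogt_celsius``: uniform background with hot-enriched residues weighted
    ``1 + s·u`` and cold-enriched ``1 − s·u`` where ``u`` maps OGT linearly
    onto [−1, 1] over 5–95 °C."""
    u = np.clip((ogt_celsius - _T_MID) / _T_HALF, -1.0, 1.0)
    w = np.ones(20)
    for i, aa in enumerate(STANDARD_AA):
        if aa in spec.hot_enriched:
            w[i] *= 1.0 + spec.enrichment_strength * u
        elif aa in spec.cold_enriched:
            w[i] *= 1.0 - spec.enrichment_strength * u
    w = np.clip(w, 1e-6, None)
    return w / w.sum()


def _draw_sequence(rng: np.random.Generator, length: int, weights: np.ndarray) -> np.ndarray:
    return rng.choice(20, size=length, p=weights)


def _adapted_copy(
    ancestor: np.ndarray,
    target_weights: np.ndarray,
    substitution_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy ``ancestor`` with a Binomial(L, rate) substitution budget.

    Substituted sites are targeted: residues over-represented relative to
    ``target_weights`` are converted into under-represented ones (drawn
    from the deficit distribution), which moves the copy's composition
    toward the target with the fewest possible changes.  Budget left over
    once the composition matches is spent on neutral substitutions drawn
    from the target distribution.
    """
    length = len(ancestor)
    budget = int(rng.binomial(length, substitution_rate))
    seq = ancestor.copy()
    if budget == 0:
        return seq
    counts = np.bincount(ancestor, minlength=20).astype(np.float64)
    target = target_weights * length
    surplus = np.maximum(counts - target, 0.0)
    deficit = np.maximum(target - counts, 0.0)
    candidates: list[int] = []
    for residue in np.flatnonzero(surplus):
        positions = np.flatnonzero(ancestor == residue)
        k = min(int(np.floor(surplus[residue])), len(positions))
        if k:
            candidates.extend(rng.choice(positions, k, replace=False).tolist())
    cand = np.array(candidates, dtype=np.intp)
    rng.shuffle(cand)
    moved = cand[:budget]
    if len(moved) and deficit.sum() > 0:
        seq[moved] = rng.choice(20, len(moved), p=deficit / deficit.sum())
    extra = budget - len(moved)
    if extra > 0:
        positions = rng.choice(length, extra, replace=False)
        seq[positions] = rng.choice(20, extra, p=target_weights)
    return seq


def _indices_to_str(indices: np.ndarray) -> str:
    return "".join(_AA_ARRAY[indices])


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[Corpus, list[OrthologCluster], dict]:
    """Generate a corpus, its ortholog clusters, and the ground truth.

    Per class, genome OGTs are uniform over the class band; each family
    copies one ancestor (drawn at the members' mean OGT) into its member
    genomes with composition-targeted per-site substitution toward the
    member's own tilted background (see :func:`_adapted_copy`); each
    genome is then filled up to ``proteins_per_genome``
    with unclustered proteins drawn entirely from its tilted background.
    The ground-truth dict records genome OGTs, per-protein family ids and
    effective (noise-jittered) temperatures for oracle checks.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    corpus = Corpus()
    corpus.provenance.append(f"synthetic corpus, seed={spec.seed}")

    genome_ids: list[str] = []
    for prefix in ("psy", "mes", "thr"):
        low, high = _CLASS_BANDS[prefix]
        for i in range(spec.n_genomes_per_class):
            gid = f"{prefix}{i + 1:02d}"
            ogt = float(rng.uniform(low, high))
            corpus.add_genome(
                GenomeRecord.from_metadata(gid, f"Synthetica {prefix}ophila {i + 1}", ogt)
            )
            genome_ids.append(gid)

    ogts = {g: corpus.genomes[g].ogt_celsius for g in genome_ids}
    spans = sorted(spec.family_span)
    span_probs = np.array([spec.family_span[s] for s in spans], dtype=float)
    lmin, lmax = spec.length_range

    serial = {g: 0 for g in genome_ids}
    family_of_protein: dict[str, str] = {}
    effective_temp: dict[str, float] = {}
    clusters: list[OrthologCluster] = []

    def next_pid(gid: str) -> str:
        serial[gid] += 1
        return f"{gid}|p{serial[gid]:04d}"

    for fam_idx in range(spec.families):
        span = int(rng.choice(spans, p=span_probs))
        members = [genome_ids[i] for i in rng.choice(len(genome_ids), span, replace=False)]
        length = int(rng.integers(lmin, lmax + 1))
        family_offset = float(rng.normal(0.0, spec.family_effect_sd))
        anc_ogt = float(np.mean([ogts[g] for g in members])) + family_offset
        ancestor = _draw_sequence(rng, length, composition_weights(anc_ogt, spec))
        cid = f"FAM{fam_idx:05d}"
        member_pids = []
        for gid in members:
            if serial[gid] >= spec.proteins_per_genome:
                raise ValueError(
                    f"infeasible spec: genome {gid} needs more than "
                    f"{spec.proteins_per_genome} proteins to host its families"
                )
            eff = ogts[gid] + family_offset + float(rng.normal(0.0, spec.label_noise_sd))
            seq = _adapted_copy(
                ancestor, composition_weights(eff, spec), spec.substitution_rate, rng
            )
            pid = next_pid(gid)
            corpus.add_protein(
                ProteinRecord(pid, gid, _indices_to_str(seq), label_celsius=ogts[gid])
            )
            family_of_protein[pid] = cid
            effective_temp[pid] = eff
            member_pids.append(pid)
        clusters.append(OrthologCluster(cid, frozenset(member_pids)))

    for gid in genome_ids:
        while serial[gid] < spec.proteins_per_genome:
            # unclustered proteins carry their own family-of-one effect
            eff = ogts[gid] + float(
                rng.normal(0.0, spec.family_effect_sd)
            ) + float(rng.normal(0.0, spec.label_noise_sd))
            length = int(rng.integers(lmin, lmax + 1))
            seq = _draw_sequence(rng, length, composition_weights(eff, spec))
            pid = next_pid(gid)
            corpus.add_protein(
                ProteinRecord(pid, gid, _indices_to_str(seq), label_celsius=ogts[gid])
            )
            effective_temp[pid] = eff

    ground_truth = {
        "genome_ogt": ogts,
        "family_of_protein": family_of_protein,
        "effective_temp": effective_temp,
        "hot_enriched": sorted(spec.hot_enriched),
        "cold_enriched": sorted(spec.cold_enriched),
    }
    return corpus, clusters, ground_truth


def write_corpus_files(
    corpus: Corpus,
    clusters: list[OrthologCluster],
    outdir: str | Path,
) -> dict[str, object]:
    """Write the corpus as one FASTA per genome, a metadata TSV, and an
    OrthoFinder-style Orthogroups.tsv.

    Output is byte-identical for identical inputs (sorted iteration, fixed
    float formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_paths = []
    by_genome: dict[str, list[ProteinRecord]] = {}
    for pid in sorted(corpus.proteins):
        p = corpus.proteins[pid]
        by_genome.setdefault(p.genome_id, []).append(p)
    for gid in sorted(corpus.genomes):
        path = outdir / f"{gid}.faa"
        with open(path, "w") as fh:
            for p in by_genome.get(gid, []):
                fh.write(f">{p.protein_id}\n{p.sequence}\n")
        fasta_paths.append(path)

    metadata_path = outdir / "metadata.tsv"
    with open(metadata_path, "w") as fh:
        fh.write("genome_id\tspecies\togt_celsius\n")
        for gid in sorted(corpus.genomes):
            g = corpus.genomes[gid]
            fh.write(f"{g.genome_id}\t{g.species}\t{g.ogt_celsius:.6f}\n")

    orthogroups_path = outdir / "Orthogroups.tsv"
    genome_order = sorted(corpus.genomes)
    with open(orthogroups_path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(genome_order) + "\n")
        for cluster in sorted(clusters, key=lambda c: c.cluster_id):
            cells = []
            for gid in genome_order:
                members = sorted(
                    pid
                    for pid in cluster.member_protein_ids
                    if corpus.proteins[pid].genome_id == gid
                )
                cells.append(", ".join(members))
            fh.write(cluster.cluster_id + "\t" + "\t".join(cells) + "\n")

    return {
        "fasta_paths": fasta_paths,
        "metadata_path": metadata_path,
        "orthogroups_path": orthogroups_path,
    }


def generate_mining_fixture(
    spec: SyntheticSpec,
    n_family_members: int = 5,
    n_decoys: int = 3,
    outdir: str | Path = ".",
    pfam_id: str = "PF00704.28",
) -> tuple[Path, Path]:
    """Write a FASTA of domain-family members plus decoys and a hand-built
    hmmsearch ``--tblout`` listing exactly the family members.

    Member sequences are substituted copies of one ancestor with effective
    temperatures spread across the full OGT range, so a trained model bins
    them into all three classes; fabricated full-sequence E-values are
    ≤ 1e−10.  Decoys are independent background sequences and do not
    appear in the tblout.  Returns ``(fasta_path, tblout_path)``.
    """
    if n_family_members < 1 or n_decoys < 0:
        raise ValueError("need n_family_members >= 1 and n_decoys >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x3117]))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lmin, lmax = spec.length_range
    length = int(rng.integers(lmin, lmax + 1))
    ancestor = _draw_sequence(rng, length, composition_weights(_T_MID, spec))

    member_temps = np.linspace(10.0, 90.0, n_family_members)
    records: list[tuple[str, str]] = []
    tbl_rows: list[tuple[str, float, float]] = []
    for i, temp in enumerate(member_temps):
        seq = _adapted_copy(
            ancestor, composition_weights(temp, spec), spec.substitution_rate, rng
        )
        pid = f"mg_{i + 1:05d}"
        records.append((pid, _indices_to_str(seq)))
        evalue = 10.0 ** -(20 + 5 * i)
        score = 150.0 + 10.0 * i
        tbl_rows.append((pid, evalue, score))
    for j in range(n_decoys):
        dl = int(rng.integers(lmin, lmax + 1))
        seq = _draw_sequence(rng, dl, composition_weights(_T_MID, spec))
        records.append((f"decoy_{j + 1:05d}", _indices_to_str(seq)))

    fasta_path = outdir / "mining_targets.faa"
    with open(fasta_path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n{seq}\n")

    tblout_path = outdir / "hits.tblout"
    query_name = pfam_id.split(".", 1)[0]
    with open(tblout_path, "w") as fh:
        fh.write("#                                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----\n")
        fh.write("# target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target\n")
        fh.write("#------------------- ---------- -------------------- ---------- --------- ------ ----- --------- ------ -----   --- --- --- --- --- --- --- --- ---------------------\n")
        for pid, evalue, score in tbl_rows:
            fh.write(
                f"{pid:<20} -          {query_name:<20} {pfam_id:<10} "
                f"{evalue:9.1e} {score:6.1f}   0.0 {evalue:9.1e} {score:6.1f}   0.0 "
                f"  1.0   1   0   0   1   1   1   1 synthetic domain hit\n"
            )
        fh.write("#\n# Program:         hmmsearch\n# Version:         3.4 (synthetic fixture)\n")
    return fasta_path, tblout_path
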