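"""Ortholog clusters and homology-aware cross-validation splits.

Homologous proteins are near-duplicates of one another; if members of one
ortholog cluster land on both sides of a train/validation boundary the
model can score well by memorising family identity rather than learning the
sequence–temperature relation.  Splitting therefore operates on whole
clusters: a cluster is assigned to exactly one fold, and only clusters
spanning at least two temperature classes enter the train/validation pool
(single-class clusters carry no cross-class signal).  All remaining
labelled proteins form the held-out test pool.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ogtpred.corpus import Corpus, TempClass

__all__ = [
    "OrthologCluster",
    "SplitPlan",
    "parse_orthogroups",
    "filter_multiclass_clusters",
    "make_split",
]


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: str
    member_protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_protein_ids:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")

    def classes_present(self, corpus: Corpus) -> set[TempClass]:
        """Temperature classes of the members' source genomes.

        Members from excluded genomes contribute nothing.  Unknown member
        ids raise ``KeyError`` naming them.
        """
        missing = sorted(pid for pid in self.member_protein_ids if pid not in corpus.proteins)
        if missing:
            raise KeyError(
                f"cluster {self.cluster_id!r} has unresolvable members: "
                + ", ".join(missing[:20])
            )
        classes = {
            corpus.genome_of(pid).temp_class
            for pid in self.member_protein_ids
        }
        classes.discard(TempClass.EXCLUDED)
        return classes


def parse_orthogroups(path: str | Path) -> list[OrthologCluster]:
    """Parse an OrthoFinder-style ``Orthogroups.tsv``.

    First column: cluster id; each further column: comma-separated protein
    ids for one genome (cells may be empty).  A header row is expected and
    skipped.  Duplicate cluster ids or a protein id occurring in two
    clusters are hard errors.
    """
    clusters: list[OrthologCluster] = []
    seen_clusters: set[str] = set()
    owner: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            next(reader)  # header
        except StopIteration:
            raise ValueError(f"orthogroups file {path} is empty") from None
        for row in reader:
            if not row or not row[0].strip():
                continue
            cid = row[0].strip()
            if cid in seen_clusters:
                raise ValueError(f"duplicate cluster id {cid!r} in {path}")
            seen_clusters.add(cid)
            members: set[str] = set()
            for cell in row[1:]:
                for pid in cell.split(","):
                    pid = pid.strip()
                    if not pid:
                        continue
                    if pid in owner:
                        raise ValueError(
                            f"protein {pid!r} appears in clusters "
                            f"{owner[pid]!r} and {cid!r}"
                        )
                    owner[pid] = cid
                    members.add(pid)
            if members:
                clusters.append(OrthologCluster(cid, frozenset(members)))
    return clusters


def filter_multiclass_clusters(
    clusters: Iterable[OrthologCluster], corpus: Corpus
) -> list[OrthologCluster]:
    """Keep clusters whose members span ≥ 2 temperature classes.

    Output is sorted by cluster_id for platform-stable downstream
    shuffling.
    """
    retained = [c for c in clusters if len(c.classes_present(corpus)) >= 2]
    return sorted(retained, key=lambda c: c.cluster_id)


@dataclass
class SplitPlan:
    """Cluster-level fold assignment plus the train/test protein partition.

    ``train_protein_ids`` is the labelled train/validation pool (members of
    retained clusters); ``test_protein_ids`` is every other labelled
    protein.  The two sets are disjoint and together cover all labelled
    proteins of the corpus the plan was built from.
    """

    fold_of_cluster: dict[str, int]
    k: int
    seed: int
    train_protein_ids: set[str]
    test_protein_ids: set[str]
    members_of_cluster: dict[str, frozenset[str]] = field(default_factory=dict)

    def clusters_in_fold(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.fold_of_cluster.items() if f == fold)

    def fold_protein_ids(self, fold: int) -> set[str]:
        """Labelled proteins of the clusters assigned to ``fold``."""
        ids: set[str] = set()
        for cid in self.clusters_in_fold(fold):
            ids |= self.members_of_cluster[cid] & self.train_protein_ids
        return ids

    def training_pool_ids(self, validation_fold: int) -> set[str]:
        """Train-pool proteins outside ``validation_fold``."""
        return self.train_protein_ids - self.fold_protein_ids(validation_fold)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "folds": {
                str(f): self.clusters_in_fold(f) for f in range(self.k)
            },
            "members_of_cluster": {
                c: sorted(m) for c, m in sorted(self.members_of_cluster.items())
            },
            "train_protein_ids": sorted(self.train_protein_ids),
            "test_protein_ids": sorted(self.test_protein_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        fold_of_cluster = {
            cid: int(f)
            for f, cids in payload["folds"].items()
            for cid in cids
        }
        return cls(
            fold_of_cluster=fold_of_cluster,
            k=int(payload["k"]),
            seed=int(payload["seed"]),
            train_protein_ids=set(payload["train_protein_ids"]),
            test_protein_ids=set(payload["test_protein_ids"]),
            members_of_cluster={
                c: frozenset(m) for c, m in payload["members_of_cluster"].items()
            },
        )


def make_split(
    clusters: Sequence[OrthologCluster],
    corpus: Corpus,
    k: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Assign retained clusters to ``k`` folds: seeded shuffle of the
    lexicographically sorted cluster list, then round-robin.

    Fold sizes differ by at most one cluster, every cluster lands in
    exactly one fold, and the same (clusters, k, seed) always reproduces
    the same plan.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(clusters) < k:
        raise ValueError(f"need at least k={k} clusters, got {len(clusters)}")
    ordered = sorted(clusters, key=lambda c: c.cluster_id)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ordered))
    fold_of_cluster = {ordered[int(i)].cluster_id: pos % k for pos, i in enumerate(perm)}

    labelled = corpus.labelled_protein_ids()
    members_of_cluster = {c.cluster_id: c.member_protein_ids for c in ordered}
    in_clusters: set[str] = set()
    for c in ordered:
        in_clusters |= c.member_protein_ids
    train_ids = labelled & in_clusters
    test_ids = labelled - in_clusters
    return SplitPlan(
        fold_of_cluster=fold_of_cluster,
        k=k,
        seed=seed,
        train_protein_ids=train_ids,
        test_protein_ids=test_ids,
        members_of_cluster=members_of_cluster,
    )
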