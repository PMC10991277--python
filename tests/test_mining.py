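"""hmmsearch tblout parsing, hit filtering, candidate ranking and export."""

import numpy as np
import pytest
from Bio import SeqIO

from ogtpred.mining import (
    DomainHit,
    export_candidates,
    filter_hits,
    mine,
    parse_hmmsearch_tblout,
)
from ogtpred.synthetic import SyntheticSpec, generate_mining_fixture

TBLOUT = """\
# hmmsearch :: search profile(s) against a sequence database
# target name  accession  query name  accession  E-value  score  bias  E-value  score  bias  exp reg clu ov env dom rep inc description
#------------- ---------- ----------- ---------- -------- ------ ----- -------- ------ ----- --- --- --- --- --- --- --- --- -----------
prot_a         -          GH18        PF00704.28 1e-30    250.1  0.0   2e-30    249.0  0.0   1.0 1 0 0 1 1 1 1 chitinase-like
prot_b         -          GH18        PF00704.28 1e-05    80.2   0.1   2e-05    79.0   0.1   1.0 1 0 0 1 1 1 1 weak hit
prot_c         -          GH18        PF00704.28 1e-12    150.0  0.0   2e-12    149.0  0.0   1.0 1 0 0 1 1 1 1 another
"""


class ConstantLengthModel:
    """Stub scorer: predicted temperature is a function of sequence length."""

    def predict(self, proteins):
        return np.array([float(len(p.sequence)) for p in proteins])


class MappedModel:
    def __init__(self, mapping):
        self.mapping = mapping

    def predict(self, proteins):
        return np.array([self.mapping[p.protein_id] for p in proteins], dtype=float)


class TestParseTblout:
    def test_data_lines_parsed_comments_ignored(self, tmp_path):
        path = tmp_path / "hits.tblout"
        path.write_text(TBLOUT)
        hits = parse_hmmsearch_tblout(path)
        assert len(hits) == 3
        assert {h.protein_id for h in hits} == {"prot_a", "prot_b", "prot_c"}
        assert all(h.pfam_id == "PF00704.28" for h in hits)

    def test_scientific_evalue_parsed(self, tmp_path):
        path = tmp_path / "hits.tblout"
        path.write_text(TBLOUT)
        by_id = {h.protein_id: h for h in parse_hmmsearch_tblout(path)}
        assert by_id["prot_a"].full_seq_evalue == pytest.approx(1e-30)
        assert by_id["prot_a"].full_seq_score == pytest.approx(250.1)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tblout"
        path.write_text("# header\nonly three fields here\n")
        with pytest.raises(ValueError, match=":2"):
            parse_hmmsearch_tblout(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "empty.tblout"
        path.write_text("# nothing but comments\n")
        with caplog.at_level("WARNING"):
            hits = parse_hmmsearch_tblout(path)
        assert hits == []
        assert "no data lines" in caplog.text

    def test_query_name_fallback_when_accession_dash(self, tmp_path):
        path = tmp_path / "hits.tblout"
        line = (
            "p1 - GH18 - 1e-10 100.0 0.0 1e-10 99.0 0.0 1.0 1 0 0 1 1 1 1 x\n"
        )
        path.write_text(line)
        (hit,) = parse_hmmsearch_tblout(path)
        assert hit.pfam_id == "GH18"


class TestFilterHits:
    def _hit(self, pid, ev, score=10.0):
        return DomainHit(pid, "PF00704", ev, score)

    def test_evalue_cutoff(self):
        hits = [self._hit("a", 1e-5), self._hit("b", 1e-1)]
        kept = filter_hits(hits, evalue_max=1e-3)
        assert [h.protein_id for h in kept] == ["a"]

    def test_dedup_keeps_best_evalue(self):
        hits = [self._hit("a", 1e-4), self._hit("a", 1e-10)]
        kept = filter_hits(hits, evalue_max=1.0)
        assert len(kept) == 1
        assert kept[0].full_seq_evalue == 1e-10

    def test_infinite_cutoff_only_dedups(self):
        hits = [self._hit("a", 5.0), self._hit("b", 2.0), self._hit("a", 1.0)]
        kept = filter_hits(hits, evalue_max=float("inf"))
        assert {h.protein_id for h in kept} == {"a", "b"}

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([], evalue_max=0.0)


class TestMine:
    def _hits(self, ids):
        return [DomainHit(i, "PF00704", 1e-10, 100.0) for i in ids]

    def test_equal_bin_fractions(self):
        seqs = {"a": "M" * 10, "b": "M" * 10, "c": "M" * 10}
        model = MappedModel({"a": 15.0, "b": 35.0, "c": 55.0})
        result = mine(self._hits(["a", "b", "c"]), seqs, model, thresholds=(20, 50))
        assert result.bin_fractions == pytest.approx(
            {"psychrophilic": 1 / 3, "mesophilic": 1 / 3, "thermophilic": 1 / 3}
        )
        assert sum(result.bin_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_rank_ties_broken_lexicographically(self):
        seqs = {"zz": "MM", "aa": "MM", "mm": "MM"}
        model = MappedModel({"zz": 80.0, "aa": 80.0, "mm": 10.0})
        result = mine(self._hits(["zz", "aa", "mm"]), seqs, model)
        assert result.ranked.iloc[0]["protein_id"] == "aa"
        assert result.ranked.iloc[0]["rank"] == 1

    def test_ranking_is_permutation_of_inputs(self):
        ids = [f"p{i}" for i in range(10)]
        seqs = {i: "M" * (5 + k) for k, i in enumerate(ids)}
        result = mine(self._hits(ids), seqs, ConstantLengthModel())
        assert sorted(result.ranked["protein_id"]) == sorted(ids)
        assert list(result.ranked["rank"]) == list(range(1, 11))
        assert result.ranked["predicted_temp"].is_monotonic_decreasing

    def test_binning_exhaustive_and_monotone_in_t_high(self):
        ids = [f"p{i}" for i in range(30)]
        seqs = {i: "M" * (3 + k) for k, i in enumerate(ids)}
        model = ConstantLengthModel()
        frac_50 = mine(self._hits(ids), seqs, model, thresholds=(10, 20))
        frac_90 = mine(self._hits(ids), seqs, model, thresholds=(10, 28))
        assert frac_90.bin_fractions["thermophilic"] <= frac_50.bin_fractions["thermophilic"]

    def test_unresolvable_protein_listed(self):
        with pytest.raises(KeyError, match="ghost"):
            mine(self._hits(["ghost"]), {"other": "MM"}, ConstantLengthModel())

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError, match="t_low < t_high"):
            mine(self._hits(["a"]), {"a": "MM"}, ConstantLengthModel(), thresholds=(50, 20))


class TestExportCandidates:
    def _result(self):
        seqs = {"a": "MKELVY", "b": "MKDDST", "c": "MKAAAA"}
        model = MappedModel({"a": 80.0, "b": 15.0, "c": 40.0})
        hits = [DomainHit(i, "PF00704", 1e-10, 50.0) for i in seqs]
        return mine(hits, seqs, model), seqs

    def test_top_one_exports_rank_one(self, tmp_path):
        result, seqs = self._result()
        fasta = tmp_path / "top.faa"
        tsv = tmp_path / "top.tsv"
        exported = export_candidates(result, 1, seqs, fasta, tsv)
        records = list(SeqIO.parse(str(fasta), "fasta"))
        assert len(records) == 1
        assert records[0].id == "a"
        assert "rank=1" in records[0].description
        assert len(exported) == 1

    def test_round_trip_sequences_identical(self, tmp_path):
        result, seqs = self._result()
        fasta = tmp_path / "top.faa"
        export_candidates(result, 3, seqs, fasta, tmp_path / "top.tsv")
        for rec in SeqIO.parse(str(fasta), "fasta"):
            assert str(rec.seq) == seqs[rec.id]

    def test_oversized_top_n_exports_all_with_warning(self, tmp_path, caplog):
        result, seqs = self._result()
        with caplog.at_level("WARNING"):
            exported = export_candidates(
                result, 99, seqs, tmp_path / "t.faa", tmp_path / "t.tsv"
            )
        assert len(exported) == 3
        assert "exporting all" in caplog.text

    def test_tsv_row_count(self, tmp_path):
        result, seqs = self._result()
        tsv = tmp_path / "top.tsv"
        export_candidates(result, 2, seqs, tmp_path / "t.faa", tsv)
        lines = tsv.read_text().strip().split("\n")
        assert len(lines) == 3  # header + 2 rows


class TestMiningFixture:
    SPEC = SyntheticSpec(
        n_genomes_per_class=2,
        proteins_per_genome=5,
        families=4,
        family_span={2: 1.0},
        length_range=(30, 40),
        seed=3,
    )

    def test_fixture_counts(self, tmp_path):
        fasta, tblout = generate_mining_fixture(self.SPEC, 5, 3, tmp_path)
        records = list(SeqIO.parse(str(fasta), "fasta"))
        assert len(records) == 8
        hits = parse_hmmsearch_tblout(tblout)
        assert len(hits) == 5

    def test_tblout_ids_are_family_members_only(self, tmp_path):
        fasta, tblout = generate_mining_fixture(self.SPEC, 5, 3, tmp_path)
        fasta_ids = {r.id for r in SeqIO.parse(str(fasta), "fasta")}
        hit_ids = {h.protein_id for h in parse_hmmsearch_tblout(tblout)}
        assert hit_ids == {i for i in fasta_ids if i.startswith("mg_")}
        assert all(h.full_seq_evalue <= 1e-10 for h in parse_hmmsearch_tblout(tblout))

    def test_mine_on_fixture_with_stub(self, tmp_path):
        fasta, tblout = generate_mining_fixture(self.SPEC, 5, 3, tmp_path)
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        hits = filter_hits(parse_hmmsearch_tblout(tblout))
        result = mine(hits, seqs, ConstantLengthModel())
        assert len(result.ranked) == 5

    def test_fixture_reproducible(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        f1, t1 = generate_mining_fixture(self.SPEC, 4, 2, d1)
        f2, t2 = generate_mining_fixture(self.SPEC, 4, 2, d2)
        assert f1.read_bytes() == f2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()
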