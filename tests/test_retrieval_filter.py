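"""Filter cascade stages, assessment contracts, and relevance stratification."""

import pytest

from assay2mol.bioassay_model import (
    BioAssayRecord,
    MoleculeOutcome,
    Outcome,
    ProteinQuery,
    TargetInfo,
)
from assay2mol.embedding_index import RetrievalResult
from assay2mol.exceptions import ContractError
from assay2mol.retrieval_filter import (
    AssayAssessment,
    RelevanceGroup,
    assess_assay,
    exclude_query_target,
    filter_min_molecules,
    filter_sequence_identity,
    relevance_ratio,
    select_assays,
)


def _record(aid, uniprot=None, n_active=2, n_other=6, sequence=None):
    actives = [MoleculeOutcome(smiles="CCO", outcome=Outcome.ACTIVE)] * n_active
    others = [MoleculeOutcome(smiles="CCN", outcome=Outcome.INACTIVE)] * n_other
    return BioAssayRecord(
        aid=aid,
        title=f"assay {aid}",
        target=TargetInfo(uniprot_id=uniprot, sequence=sequence) if uniprot else None,
        outcomes=actives + others,
    )


def _results(aids):
    return RetrievalResult([(aid, 1.0 - 0.01 * i) for i, aid in enumerate(aids)])


class TestExcludeQueryTarget:
    def test_matching_accession_removed(self):
        corpus = {1: _record(1, uniprot="P32298"), 2: _record(2, uniprot="P11111")}
        query = ProteinQuery(description="GRK4 kinase", uniprot_id="P32298")
        assert exclude_query_target(_results([1, 2]), query, corpus).aids == [2]

    def test_no_accession_is_noop(self):
        corpus = {1: _record(1, uniprot="P32298")}
        query = ProteinQuery(description="some phenotype")
        result = exclude_query_target(_results([1]), query, corpus)
        assert result.aids == [1]

    def test_three_of_twenty_excluded(self):
        corpus = {
            aid: _record(aid, uniprot="P00001" if aid <= 3 else f"P{aid:05d}")
            for aid in range(1, 21)
        }
        query = ProteinQuery(description="q", uniprot_id="P00001")
        survivors = exclude_query_target(_results(range(1, 21)), query, corpus)
        assert len(survivors) == 17
        assert set(survivors.aids) == set(range(4, 21))


class TestFilterMinMolecules:
    def test_boundary_is_inclusive(self):
        corpus = {1: _record(1, n_active=2, n_other=4)}  # table of 6
        assert filter_min_molecules(_results([1]), corpus, 6, n_mol=2).aids == [1]
        assert filter_min_molecules(_results([1]), corpus, 7, n_mol=2).aids == []

    def test_no_actives_escalates_to_twice_n_mol(self):
        corpus = {1: _record(1, n_active=0, n_other=15)}  # 2*8 - 1 rows, zero actives
        assert filter_min_molecules(_results([1]), corpus, 4, n_mol=8).aids == []
        corpus[1] = _record(1, n_active=0, n_other=16)
        assert filter_min_molecules(_results([1]), corpus, 4, n_mol=8).aids == [1]

    def test_matches_predicate_scan(self, corpus_records, corpus_manifest):
        corpus = {r.aid: r for r in corpus_records}
        results = _results([r.aid for r in corpus_records])
        survivors = filter_min_molecules(results, corpus, 10, n_mol=8)
        expected = [
            t.aid
            for t in corpus_manifest.assays.values()
            if t.table_len >= (10 if t.n_actives > 0 else 16)
        ]
        assert survivors.aids == expected


class TestFilterSequenceIdentity:
    @staticmethod
    def _provider(table):
        return lambda q, t: table[t]

    def test_exact_threshold_retained_strictly_above_removed(self):
        corpus = {
            1: _record(1, uniprot="P1", sequence="ACDEF"),
            2: _record(2, uniprot="P2", sequence="GHIKL"),
        }
        query = ProteinQuery(description="q", sequence="MNPQR")
        provider = self._provider({"ACDEF": 0.30, "GHIKL": 0.31})
        survivors = filter_sequence_identity(_results([1, 2]), query, corpus, 0.30, provider)
        assert survivors.aids == [1]

    def test_identical_protein_removed(self):
        corpus = {1: _record(1, uniprot="P1", sequence="ACDEF")}
        query = ProteinQuery(description="q", sequence="ACDEF")
        survivors = filter_sequence_identity(
            _results([1]), query, corpus, 0.30, self._provider({"ACDEF": 1.0})
        )
        assert survivors.aids == []

    def test_missing_sequence_passes_with_warning(self, caplog):
        corpus = {1: _record(1, uniprot="P1")}
        query = ProteinQuery(description="q", sequence="ACDEF")
        with caplog.at_level("WARNING"):
            survivors = filter_sequence_identity(
                _results([1]), query, corpus, 0.30, self._provider({})
            )
        assert survivors.aids == [1]
        assert "no target sequence" in caplog.text

    def test_planted_values_match_predicate_scan(self):
        import numpy as np

        rng = np.random.default_rng(8)
        corpus, table = {}, {}
        for aid in range(1, 31):
            seq = f"SEQ{aid}"
            corpus[aid] = _record(aid, uniprot=f"P{aid}", sequence="ACD" + "E" * aid)
            table["ACD" + "E" * aid] = float(rng.uniform(0, 1))
        query = ProteinQuery(description="q", sequence="MNPQR")
        survivors = filter_sequence_identity(
            _results(range(1, 31)), query, corpus, 0.30, self._provider(table)
        )
        expected = [
            aid for aid in range(1, 31) if table[corpus[aid].target.sequence] <= 0.30
        ]
        assert survivors.aids == expected


class _ScriptedProvider:
    def __init__(self, replies):
        self.replies = list(replies)

    def complete(self, prompt, kind="generate"):
        return self.replies.pop(0)


class TestAssessAssay:
    def test_scripted_verdict_passthrough(self):
        provider = _ScriptedProvider(["RELEVANT: yes\nCOUNTERSCREEN: no"])
        result = assess_assay(_record(1, uniprot="P1"), ProteinQuery(description="q"), provider)
        assert (result.relevant, result.counterscreen) == (True, False)

    def test_malformed_twice_defaults_false_with_warning(self, caplog):
        provider = _ScriptedProvider(["garbled", "still garbled"])
        with caplog.at_level("WARNING"):
            result = assess_assay(_record(1, uniprot="P1"), ProteinQuery(description="q"), provider)
        assert (result.relevant, result.counterscreen) == (False, False)
        assert "unparsable" in caplog.text

    def test_reask_once_then_succeed(self):
        provider = _ScriptedProvider(["nope", "RELEVANT: no\nCOUNTERSCREEN: yes"])
        result = assess_assay(_record(1, uniprot="P1"), ProteinQuery(description="q"), provider)
        assert (result.relevant, result.counterscreen) == (False, True)


class TestSelectAssays:
    @staticmethod
    def _assessments(n_relevant, n_total, counterscreen_aids=()):
        return [
            AssayAssessment(
                aid=i, relevant=i <= n_relevant, counterscreen=i in counterscreen_aids
            )
            for i in range(1, n_total + 1)
        ]

    def test_truncates_at_cap_in_similarity_order(self):
        assessments = self._assessments(12, 12)
        selected = select_assays(_results(range(1, 13)), assessments, 10)
        assert [a.aid for a in selected] == list(range(1, 11))

    def test_zero_relevant_yields_empty(self):
        selected = select_assays(_results(range(1, 6)), self._assessments(0, 5), 10)
        assert selected == []

    def test_counterscreens_retained_and_tagged(self):
        assessments = self._assessments(0, 5, counterscreen_aids={3})
        selected = select_assays(_results(range(1, 6)), assessments, 10)
        assert [a.aid for a in selected] == [3]
        assert selected[0].counterscreen

    def test_matches_filter_then_truncate_oracle(self):
        assessments = self._assessments(7, 15, counterscreen_aids={9, 14})
        selected = select_assays(_results(range(1, 16)), assessments, 5)
        oracle = [a for a in assessments if a.relevant or a.counterscreen][:5]
        assert [a.aid for a in selected] == [a.aid for a in oracle]


class TestRelevanceRatio:
    def test_seven_of_ten_is_high(self):
        x, group = relevance_ratio(TestSelectAssays._assessments(7, 10))
        assert x == pytest.approx(0.7)
        assert group is RelevanceGroup.HIGH

    def test_one_of_ten_is_none(self):
        x, group = relevance_ratio(TestSelectAssays._assessments(1, 10))
        assert x == pytest.approx(0.1)
        assert group is RelevanceGroup.NONE

    def test_exhaustive_enumeration_matches_inequality_table(self):
        def oracle(x):
            if x >= 0.7:
                return RelevanceGroup.HIGH
            if 0.4 < x < 0.7:
                return RelevanceGroup.MEDIUM
            if 0.1 < x <= 0.4:
                return RelevanceGroup.LOW
            return RelevanceGroup.NONE

        for n_relevant in range(11):
            x, group = relevance_ratio(TestSelectAssays._assessments(n_relevant, 10))
            assert x == pytest.approx(n_relevant / 10)
            assert group is oracle(n_relevant / 10)

    def test_empty_set_rejected(self):
        with pytest.raises(ContractError):
            relevance_ratio([])
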