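"""Size pruning, class-balanced selection, table rendering, prompt assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assay2mol.bioassay_model import (
    Measurement,
    MoleculeOutcome,
    Outcome,
    ProteinQuery,
    Relation,
    heavy_atom_count,
)
from assay2mol.context_builder import (
    COUNTERSCREEN_AVOIDANCE,
    ContextBlock,
    MoleculeSelection,
    PromptMode,
    build_prompt,
    prune_by_size,
    render_table,
    select_molecules,
    summarize_assay,
)
from assay2mol.exceptions import ContractError
from assay2mol.synthetic_corpus import MockTextProvider


def _rows(n_active, n_other, pool, offset=0):
    rows = []
    for i in range(n_active):
        rows.append(MoleculeOutcome(smiles=pool[(offset + i) % len(pool)], outcome=Outcome.ACTIVE))
    for i in range(n_other):
        label = Outcome.INACTIVE if i % 2 else Outcome.UNSPECIFIED
        rows.append(
            MoleculeOutcome(smiles=pool[(offset + n_active + i) % len(pool)], outcome=label)
        )
    return rows


class TestPruneBySize:
    def test_exactly_at_ceiling_retained(self):
        rows = [MoleculeOutcome(smiles="C" * 45, outcome=Outcome.ACTIVE)]
        assert prune_by_size(rows, 45) == rows
        assert prune_by_size(rows, 44) == []

    def test_empty_table(self):
        assert prune_by_size([], 45) == []

    def test_matches_predicate_scan(self, pool):
        rows = _rows(10, 30, pool)
        pruned = prune_by_size(rows, 15)
        assert pruned == [r for r in rows if heavy_atom_count(r.smiles) <= 15]


class TestSelectMolecules:
    def test_oversupplied_actives_balanced_at_n_mol(self, pool):
        selection = select_molecules(_rows(12, 30, pool), n_mol=8, seed=0)
        assert len(selection.actives) == 8
        assert len(selection.others) == 8
        assert not selection.all_mode

    def test_undersupply_takes_everything(self, pool):
        selection = select_molecules(_rows(3, 3, pool), n_mol=8, seed=0)
        assert len(selection.actives) == 3
        assert len(selection.others) == 3

    def test_no_actives_doubles_fallback_sample(self, pool):
        selection = select_molecules(_rows(0, 20, pool), n_mol=8, seed=0)
        assert selection.all_mode
        assert len(selection.actives) == 0
        assert len(selection.others) == 16

    def test_no_actives_small_table_takes_all(self, pool):
        selection = select_molecules(_rows(0, 10, pool), n_mol=8, seed=0)
        assert selection.all_mode
        assert len(selection.others) == 10

    def test_empty_table_is_contract_error(self):
        with pytest.raises(ContractError):
            select_molecules([], n_mol=8, seed=0)

    def test_same_seed_identical_different_seeds_differ(self, pool):
        rows = _rows(40, 60, pool)
        a = select_molecules(rows, n_mol=8, seed=5)
        b = select_molecules(rows, n_mol=8, seed=5)
        assert [r.smiles for r in a.rows] == [r.smiles for r in b.rows]
        others = {
            tuple(r.smiles for r in select_molecules(rows, 8, seed=s).rows) for s in range(10)
        }
        assert len(others) > 1

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        n_active=st.integers(0, 30),
        n_other=st.integers(0, 60),
        n_mol=st.integers(1, 10),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_selection_invariants(self, n_active, n_other, n_mol, seed):
        pool = ["C" * (i + 1) for i in range(8)]  # cheap alkanes, parse once
        rows = _rows(n_active, n_other, pool)
        if not rows:
            return
        selection = select_molecules(rows, n_mol=n_mol, seed=seed)
        assert len(selection.actives) <= n_mol
        if selection.all_mode:
            assert len(selection.actives) == 0
            assert len(selection.others) == min(n_other, 2 * n_mol)
        else:
            assert len(selection.actives) == min(n_active, n_mol)
            assert len(selection.others) == min(n_other, n_mol)


class TestRenderTable:
    ROWS = [
        MoleculeOutcome(smiles="CCN", outcome=Outcome.INACTIVE),
        MoleculeOutcome(
            smiles="CC(=O)Oc1ccccc1C(=O)O",
            outcome=Outcome.ACTIVE,
            measurement=Measurement(std_type="IC50", relation=Relation.EQ, value=3.2, units="uM"),
        ),
        MoleculeOutcome(smiles="c1ccccc1", outcome=Outcome.UNSPECIFIED),
    ]

    GOLDEN = (
        "SMILES                | Outcome     | Type | Rel | Value | Units\n"
        "----------------------+-------------+------+-----+-------+------\n"
        "CC(=O)Oc1ccccc1C(=O)O | Active      | IC50 | =   | 3.2   | uM\n"
        "CCN                   | Inactive    |      |     |       |\n"
        "c1ccccc1              | Unspecified |      |     |       |"
    )

    def test_one_row_header_plus_data_line(self):
        text = render_table([self.ROWS[0]])
        assert len(text.splitlines()) == 3  # header, rule, one data row

    def test_missing_measurement_leaves_columns_empty(self):
        lines = render_table([self.ROWS[0]]).splitlines()
        assert lines[2].startswith("CCN")
        assert "IC50" not in lines[2]

    def test_actives_first_and_golden_snapshot(self):
        assert render_table(self.ROWS) == self.GOLDEN

    def test_byte_identical_across_runs(self):
        assert render_table(self.ROWS) == render_table(self.ROWS)

    def test_selection_rendering_respects_selection_order(self, pool):
        selection = select_molecules(_rows(3, 5, pool), n_mol=4, seed=0)
        lines = render_table(selection).splitlines()[2:]
        assert [ln.split(" | ")[0].strip() for ln in lines] == [
            r.smiles for r in selection.rows
        ]


class TestSummarize:
    def test_deterministic_passthrough(self, corpus_records, corpus_manifest):
        provider = MockTextProvider()
        query = ProteinQuery(description="q")
        record = corpus_records[0]
        a = summarize_assay(record, query, provider)
        b = summarize_assay(record, query, provider)
        assert a == b
        assert str(record.aid) in a

    def test_counterscreen_gets_avoidance_clause(self, corpus_records):
        provider = MockTextProvider()
        query = ProteinQuery(description="q")
        summary = summarize_assay(corpus_records[0], query, provider, counterscreen=True)
        assert summary.endswith(COUNTERSCREEN_AVOIDANCE)


def _block(aid, pool, counterscreen=False, n_active=2):
    selection = select_molecules(_rows(n_active, 4, pool, offset=aid), n_mol=4, seed=aid)
    return ContextBlock(
        aid=aid,
        summary=f"summary {aid}",
        table_text=render_table(selection),
        selection=selection,
        counterscreen=counterscreen,
    )


class TestBuildPrompt:
    QUERY = ProteinQuery(description="serine protease inhibitor target")

    def test_zero_blocks_gives_description_only_prompt(self):
        context = build_prompt(self.QUERY, [])
        assert "Assay context" not in context.prompt
        assert self.QUERY.description in context.prompt

    def test_pure_function_of_inputs(self, pool):
        blocks = [_block(1, pool), _block(2, pool)]
        a = build_prompt(self.QUERY, blocks)
        b = build_prompt(self.QUERY, blocks)
        assert a.prompt == b.prompt
        assert a.context_hash == b.context_hash

    def test_optimize_mode_includes_all_targets_verbatim(self, pool):
        targets = pool[:5]
        context = build_prompt(
            self.QUERY,
            [_block(1, pool)],
            mode=PromptMode.OPTIMIZE_ANTI_TARGET,
            optimization_targets=targets,
        )
        for smiles in targets:
            assert smiles in context.prompt

    def test_optimize_mode_requires_targets(self):
        with pytest.raises(ContractError):
            build_prompt(self.QUERY, [], mode=PromptMode.OPTIMIZE_ANTI_TARGET)

    def test_over_budget_drops_lowest_ranked_blocks(self, pool, caplog):
        blocks = [_block(i, pool) for i in range(1, 6)]
        with caplog.at_level("WARNING"):
            context = build_prompt(self.QUERY, blocks, max_tokens=250)
        assert len(context.blocks) < 5
        assert context.blocks == blocks[: len(context.blocks)]  # lowest ranks dropped
        assert "token budget" in caplog.text

    def test_avoid_molecules_only_from_counterscreen_blocks(self, pool):
        clean = _block(1, pool)
        counter = _block(2, pool, counterscreen=True)
        context = build_prompt(self.QUERY, [clean, counter])
        expected = [r.smiles for r in counter.selection.actives]
        assert context.avoid_molecules == expected
        assert all(s in context.prompt for s in expected)
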