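"""Metric definitions against brute-force oracles, aggregation, mock scorers."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from assay2mol.evaluation import (
    MockDockingScorer,
    PlantedDockingScorer,
    aggregate,
    context_similarity,
    diversity,
    evaluate_target,
    high_affinity_fraction,
    improvement_over_baseline,
    qed_score,
    sa_score_normalized,
    score_with,
)
from assay2mol.exceptions import ContractError, UndefinedMetricError

_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _bits(smiles):
    return set(_gen.GetFingerprint(Chem.MolFromSmiles(smiles)).GetOnBits())


def _tanimoto_sets(a, b):
    return len(a & b) / len(a | b)


class TestDiversity:
    def test_identical_molecules_zero(self):
        assert diversity(["CCO"] * 5) == 0.0

    def test_disjoint_bitsets_one(self):
        a, b = "CCCCCCCC", "c1ccncc1"
        assert not (_bits(a) & _bits(b))
        assert diversity([a, b]) == 1.0

    def test_matches_double_loop_oracle(self, pool):
        rng = np.random.default_rng(0)
        mols = [pool[i] for i in rng.choice(len(pool), 10, replace=False)]
        bits = [_bits(s) for s in mols]
        total, pairs = 0.0, 0
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                total += 1.0 - _tanimoto_sets(bits[i], bits[j])
                pairs += 1
        assert diversity(mols) == pytest.approx(total / pairs, abs=1e-12)

    def test_permutation_invariant(self, pool):
        mols = pool[:8]
        assert diversity(mols) == pytest.approx(diversity(mols[::-1]), abs=1e-12)

    def test_fewer_than_two_undefined(self):
        with pytest.raises(UndefinedMetricError):
            diversity(["CCO"])


class TestHighAffinity:
    def test_all_better_saturates(self):
        assert high_affinity_fraction([-9, -8.5], -8) == 1.0

    def test_boundary_is_strict(self):
        assert high_affinity_fraction([-8, -7, -6], -7) == pytest.approx(1 / 3)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores = rng.normal(-7, 1, size=20).tolist()
            ref = float(rng.normal(-7, 1))
            expected = sum(1 for s in scores if s < ref) / 20
            assert high_affinity_fraction(scores, ref) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariant(self):
        scores = [-8.0, -7.0, -6.5, -9.1]
        assert high_affinity_fraction(scores, -7.2) == high_affinity_fraction(
            scores[::-1], -7.2
        )


class TestImprovement:
    def test_null_improvement(self):
        assert improvement_over_baseline([-7.0, -7.0], [-7.0]) == 0.0

    def test_unit_shift(self):
        assert improvement_over_baseline([-8.0] * 4, [-7.0, -7.0]) == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            gen = rng.normal(-7.5, 1, size=15)
            base = rng.normal(-7, 1, size=8)
            expected = float(np.mean(base)) - float(np.mean(gen))
            assert improvement_over_baseline(gen.tolist(), base.tolist()) == pytest.approx(
                expected, abs=1e-12
            )

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        gen = rng.normal(size=10).tolist()
        base = rng.normal(size=5).tolist()
        shifted = improvement_over_baseline([g + 3.3 for g in gen], [b + 3.3 for b in base])
        assert shifted == pytest.approx(improvement_over_baseline(gen, base), abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ContractError):
            improvement_over_baseline([], [-7.0])


class TestContextSimilarity:
    def test_identical_molecule_scores_one(self):
        assert context_similarity(["CCO"], ["CCO", "CCN"])[0] == 1.0

    def test_disjoint_pair_scores_zero(self):
        assert context_similarity(["CCCCCCCC"], ["c1ccncc1"])[0] == 0.0

    def test_matches_matrix_oracle(self, pool):
        generated, context = pool[:5], pool[5:10]
        gen_bits = [_bits(s) for s in generated]
        ctx_bits = [_bits(s) for s in context]
        oracle = [max(_tanimoto_sets(g, c) for c in ctx_bits) for g in gen_bits]
        assert context_similarity(generated, context) == pytest.approx(oracle, abs=1e-12)


class TestPerMoleculeMetrics:
    def test_qed_and_sa_in_unit_interval(self, pool):
        for smiles in pool[:30]:
            assert 0.0 <= qed_score(smiles) <= 1.0
            assert 0.0 <= sa_score_normalized(smiles) <= 1.0

    def test_sa_orientation_easy_molecule_scores_high(self):
        # 0 = hardest to synthesize, so a plain alkane must score near 1
        assert sa_score_normalized("CCCCCC") > 0.7
        assert sa_score_normalized("CCCCCC") > sa_score_normalized(
            "CC1(C)C2CCC1(C)C(=O)C2OC1OC(C(=O)O)C(O)C(O)C1O"  # fused, stereocenter-rich
        )


class TestScorers:
    def test_mock_scorer_deterministic(self):
        a = MockDockingScorer(seed=4).score("CCO", "t1")
        b = MockDockingScorer(seed=4).score("CCO", "t1")
        assert a == b
        assert MockDockingScorer(seed=5).score("CCO", "t1") != a

    def test_invalid_molecules_skipped_with_count(self, caplog):
        with caplog.at_level("WARNING"):
            scores = score_with(MockDockingScorer(), ["CCO", "@@bad@@", "CCN"], "t")
        assert set(scores) == {"CCO", "CCN"}
        assert "skipped 1" in caplog.text

    def test_planted_scorer_rewards_similarity_to_actives(self, pool):
        actives = pool[40:50]
        scorer = PlantedDockingScorer({"t": actives}, seed=0, noise=0.0, effect=3.0)
        base = MockDockingScorer(seed=0, spread=0.0)
        for smiles in actives:
            assert scorer.score(smiles, "t") == pytest.approx(base.score(smiles, "t") - 3.0)


class TestAggregation:
    def test_single_target_single_molecule_identity(self):
        report = evaluate_target("t", ["CCO"])
        summary = aggregate([report])
        assert summary["qed"]["mean_of_means"] == pytest.approx(qed_score("CCO"))
        assert summary["size"]["median_of_medians"] == 3

    def test_two_target_mean(self, pool):
        r1 = evaluate_target("a", [pool[0]])
        r2 = evaluate_target("b", [pool[1]])
        summary = aggregate([r1, r2])
        expected = (qed_score(pool[0]) + qed_score(pool[1])) / 2
        assert summary["qed"]["mean_of_means"] == pytest.approx(expected)

    def test_two_level_equals_flat_for_equal_counts_mean(self, pool):
        groups = [pool[:4], pool[4:8], pool[8:12]]
        reports = [evaluate_target(f"t{i}", g) for i, g in enumerate(groups)]
        summary = aggregate(reports)
        flat = float(np.mean([qed_score(s) for g in groups for s in g]))
        assert summary["qed"]["mean_of_means"] == pytest.approx(flat, abs=1e-12)

    def test_matches_independent_two_level_recomputation(self, pool):
        rng = np.random.default_rng(7)
        reports = []
        per_target_means, per_target_medians = [], []
        for i in range(5):
            mols = [pool[j] for j in rng.choice(len(pool), 6, replace=False)]
            reports.append(evaluate_target(f"t{i}", mols))
            sizes = [float(Chem.MolFromSmiles(s).GetNumHeavyAtoms()) for s in mols]
            per_target_means.append(np.mean(sizes))
            per_target_medians.append(np.median(sizes))
        summary = aggregate(reports)
        assert summary["size"]["mean_of_means"] == pytest.approx(np.mean(per_target_means))
        assert summary["size"]["median_of_means"] == pytest.approx(np.median(per_target_means))
        assert summary["size"]["median_of_medians"] == pytest.approx(
            np.median(per_target_medians)
        )

    def test_empty_report_list_rejected(self):
        with pytest.raises(ContractError):
            aggregate([])
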