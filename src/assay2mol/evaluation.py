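"""Metric suite for generated molecules and pluggable activity scorers.

Per-molecule metrics: drug-likeness (QED, in [0, 1]), normalized synthetic
accessibility (SA, affinely rescaled from the raw 1-10 fragment-complexity
score to [0, 1] with 0 hardest to synthesize), heavy-atom size, and optional
docking / anti-target scores from a registered scorer.

Set-level metrics: Diversity (mean pairwise Tanimoto *distance* between
Morgan fingerprints, radius 2 / 2048 bits), High Affinity (fraction of
generated molecules scoring strictly better, i.e. lower, than the reference),
improvement over a per-target background score distribution, and max
similarity of each generated molecule to the prompt's context molecules.

Aggregation is two-level: average metrics per target first, then mean and
median of those per-target values across targets.

Docking engines and anti-target predictors are external; this module defines
the scorer interface and ships deterministic mocks (a hash-based scorer and a
"planted" scorer that rewards similarity to a known active set, used to test
that relevant context measurably helps).
"""

from __future__ import annotations

import hashlib
import logging
import statistics
import sys
import os
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDConfig
from rdkit.Chem import QED, rdFingerprintGenerator

from .bioassay_model import canonicalize_smiles, heavy_atom_count, is_valid_smiles
from .exceptions import ContractError, InvalidSmilesError, UndefinedMetricError

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, path-injected)

logger = logging.getLogger(__name__)

_MORGAN_RADIUS = 2
_MORGAN_BITS = 2048
_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=_MORGAN_RADIUS, fpSize=_MORGAN_BITS
)


def _fingerprint(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES: {smiles!r}")
    return _fp_generator.GetFingerprint(mol)


def qed_score(smiles: str) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1]."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES: {smiles!r}")
    return float(QED.qed(mol))


def sa_score_normalized(smiles: str) -> float:
    """Synthetic accessibility mapped to [0, 1]; 0 = hardest to synthesize.

    The raw fragment-contribution score lives on a 1 (easy) to 10 (hard)
    scale; the affine map ``1 - (raw - 1) / 9`` flips and rescales it.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES: {smiles!r}")
    raw = sascorer.calculateScore(mol)
    return float(1.0 - (raw - 1.0) / 9.0)


def tanimoto_similarity(smiles_a: str, smiles_b: str) -> float:
    return float(DataStructs.TanimotoSimilarity(_fingerprint(smiles_a), _fingerprint(smiles_b)))


def diversity(smiles_list: Sequence[str]) -> float:
    """Mean pairwise Tanimoto distance over all unordered molecule pairs."""
    if len(smiles_list) < 2:
        raise UndefinedMetricError("diversity requires at least 2 molecules")
    fps = [_fingerprint(s) for s in smiles_list]
    n = len(fps)
    total = 0.0
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        total += sum(1.0 - s for s in sims)
    return total / (n * (n - 1) / 2)


def high_affinity_fraction(gen_scores: Sequence[float], ref_score: float) -> float:
    """Fraction of generated molecules scoring strictly lower than the reference."""
    if not gen_scores:
        raise ContractError("high affinity fraction undefined for empty score list")
    return sum(1 for s in gen_scores if s < ref_score) / len(gen_scores)


def improvement_over_baseline(
    gen_scores: Sequence[float], baseline_scores: Sequence[float]
) -> float:
    """Mean docking-score improvement over a per-target background.

    ``mean(baseline) - mean(generated)``: positive values mean the generated
    molecules score better (lower) than the background distribution.  The
    statistic is invariant to shifting all scores by a constant.
    """
    if not gen_scores or not baseline_scores:
        raise ContractError("improvement requires non-empty score lists")
    baseline_mean = float(np.mean(baseline_scores))
    return float(np.mean([baseline_mean - s for s in gen_scores]))


def context_similarity(
    generated: Sequence[str], context_molecules: Sequence[str]
) -> list[float]:
    """Per generated molecule: max Tanimoto similarity to any context molecule."""
    if not generated or not context_molecules:
        raise ContractError("context similarity requires non-empty molecule lists")
    context_fps = [_fingerprint(s) for s in context_molecules]
    out = []
    for s in generated:
        fp = _fingerprint(s)
        out.append(float(max(DataStructs.BulkTanimotoSimilarity(fp, context_fps))))
    return out


# ---------------------------------------------------------------------------
# Scorer interface and mocks


@runtime_checkable
class Scorer(Protocol):
    """External activity scorer: (canonical SMILES, target id) -> score."""

    def score(self, smiles: str, target_id: str) -> float: ...


class MockDockingScorer:
    """Deterministic hash-based stand-in for a docking engine.

    Scores are drawn from roughly N(center, spread) as a pure function of
    (canonical SMILES, target id, seed): the same molecule/target pair always
    scores identically, different pairs decorrelate.
    """

    def __init__(self, seed: int = 0, center: float = -7.0, spread: float = 1.0):
        self.seed, self.center, self.spread = seed, center, spread

    def _unit(self, smiles: str, target_id: str) -> float:
        digest = hashlib.blake2b(
            f"{self.seed}|{target_id}|{smiles}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(digest, "big") / 2**64

    def score(self, smiles: str, target_id: str) -> float:
        # inverse-normal via two hashed uniforms (Box-Muller, one branch)
        u1 = max(self._unit(smiles, target_id), 1e-12)
        u2 = self._unit(smiles, target_id + "#2")
        z = float(np.sqrt(-2 * np.log(u1)) * np.cos(2 * np.pi * u2))
        return self.center + self.spread * z


class PlantedDockingScorer(MockDockingScorer):
    """Mock scorer with a planted structure-activity signal.

    Molecules similar (Morgan/Tanimoto) to a target-specific known-active set
    score lower (better) by up to ``effect`` kcal/mol, on top of small
    hash-based noise.  Pipelines that surface the right context molecules —
    and generators that learn from them — therefore measurably beat
    context-free generation, mirroring how real screening context should
    transfer.
    """

    def __init__(
        self,
        known_actives: dict[str, Sequence[str]],
        seed: int = 0,
        center: float = -7.0,
        noise: float = 0.3,
        effect: float = 3.0,
    ):
        super().__init__(seed=seed, center=center, spread=noise)
        self.effect = effect
        self._active_fps = {
            target: [_fingerprint(s) for s in smiles_list]
            for target, smiles_list in known_actives.items()
        }

    def score(self, smiles: str, target_id: str) -> float:
        base = super().score(smiles, target_id)
        fps = self._active_fps.get(target_id)
        if not fps:
            return base
        sim = max(DataStructs.BulkTanimotoSimilarity(_fingerprint(smiles), fps))
        return base - self.effect * sim


def score_with(
    scorer: Scorer, molecules: Sequence[str], target_id: str
) -> dict[str, float]:
    """Score each valid molecule; invalid molecules are skipped with a warning."""
    scores: dict[str, float] = {}
    skipped = 0
    for smiles in molecules:
        if not is_valid_smiles(smiles):
            skipped += 1
            continue
        canonical = canonicalize_smiles(smiles)
        try:
            scores[canonical] = float(scorer.score(canonical, target_id))
        except Exception as e:  # noqa: BLE001 - external scorer may fail per molecule
            logger.warning("scorer failed on %s: %s", canonical, e)
    if skipped:
        logger.warning("skipped %d invalid molecules during scoring", skipped)
    return scores


# ---------------------------------------------------------------------------
# Reports and aggregation


@dataclass
class TargetReport:
    """Per-target evaluation: per-molecule metric table plus set-level stats."""

    target_id: str
    per_molecule: pd.DataFrame  # columns: smiles, qed, sa_norm, size[, dock_score]
    diversity: Optional[float] = None
    high_affinity: Optional[float] = None
    improvement: Optional[float] = None
    relevance_group: Optional[str] = None
    context_similarity_stats: dict[str, float] = field(default_factory=dict)

    def metric_means(self) -> dict[str, float]:
        return {c: float(self.per_molecule[c].mean()) for c in self._metric_columns()}

    def metric_medians(self) -> dict[str, float]:
        return {c: float(self.per_molecule[c].median()) for c in self._metric_columns()}

    def _metric_columns(self) -> list[str]:
        return [c for c in self.per_molecule.columns if c != "smiles"]


def evaluate_target(
    target_id: str,
    molecules: Sequence[str],
    scorer: Optional[Scorer] = None,
    ref_score: Optional[float] = None,
    baseline_scores: Optional[Sequence[float]] = None,
    context_molecules: Optional[Sequence[str]] = None,
    relevance_group: Optional[str] = None,
) -> TargetReport:
    """Compute the full metric table for one target's generated molecules."""
    valid = [canonicalize_smiles(s) for s in molecules if is_valid_smiles(s)]
    if not valid:
        raise ContractError("no valid molecules to evaluate")
    rows = [
        {
            "smiles": s,
            "qed": qed_score(s),
            "sa_norm": sa_score_normalized(s),
            "size": heavy_atom_count(s),
        }
        for s in valid
    ]
    report = TargetReport(
        target_id=target_id,
        per_molecule=pd.DataFrame(rows),
        relevance_group=relevance_group,
    )
    if len(valid) >= 2:
        report.diversity = diversity(valid)
    if scorer is not None:
        scores = score_with(scorer, valid, target_id)
        report.per_molecule["dock_score"] = [scores[s] for s in valid]
        score_values = list(scores.values())
        if ref_score is not None:
            report.high_affinity = high_affinity_fraction(score_values, ref_score)
        if baseline_scores:
            report.improvement = improvement_over_baseline(score_values, baseline_scores)
    if context_molecules:
        sims = context_similarity(valid, context_molecules)
        report.context_similarity_stats = {
            "mean": float(np.mean(sims)),
            "median": float(np.median(sims)),
            "max": float(np.max(sims)),
        }
    return report


def aggregate(reports: Sequence[TargetReport]) -> dict[str, dict[str, float]]:
    """Two-level aggregation across targets.

    Per-target means (and medians) are computed first; the cross-target
    summary is then the mean and median of those per-target statistics.
    Output: ``{metric: {mean_of_means, median_of_means, mean_of_medians,
    median_of_medians}}`` plus set-level metrics where present.
    """
    if not reports:
        raise ContractError("aggregate requires at least one target report")
    metrics: dict[str, dict[str, list[float]]] = {}
    for report in reports:
        for name, value in report.metric_means().items():
            metrics.setdefault(name, {}).setdefault("means", []).append(value)
        for name, value in report.metric_medians().items():
            metrics.setdefault(name, {}).setdefault("medians", []).append(value)
    for attr in ("diversity", "high_affinity", "improvement"):
        values = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        if values:
            metrics.setdefault(attr, {})["means"] = values
            metrics[attr]["medians"] = values
    out = {}
    for name, groups in metrics.items():
        summary = {}
        if "means" in groups:
            summary["mean_of_means"] = float(np.mean(groups["means"]))
            summary["median_of_means"] = float(statistics.median(groups["means"]))
        if "medians" in groups:
            summary["mean_of_medians"] = float(np.mean(groups["medians"]))
            summary["median_of_medians"] = float(statistics.median(groups["medians"]))
        out[name] = summary
    return out


def improvement_by_group(
    reports: Sequence[TargetReport],
) -> dict[str, dict[str, float]]:
    """Average and median improvement stratified by relevance group."""
    groups: dict[str, list[float]] = {}
    for r in reports:
        if r.improvement is not None and r.relevance_group is not None:
            groups.setdefault(r.relevance_group, []).append(r.improvement)
    return {
        g: {"mean": float(np.mean(v)), "median": float(statistics.median(v))}
        for g, v in groups.items()
    }


def report_to_json_dict(report: TargetReport) -> dict:
    """Stable JSON-serializable form of a target report (byte-identical reruns)."""
    return {
        "target_id": report.target_id,
        "per_molecule": report.per_molecule.round(10).to_dict(orient="records"),
        "diversity": report.diversity,
        "high_affinity": report.high_affinity,
        "improvement": report.improvement,
        "relevance_group": report.relevance_group,
        "context_similarity_stats": report.context_similarity_stats,
    }
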