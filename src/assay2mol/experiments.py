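"""Reproducible offline studies run entirely against the deterministic mocks.

These functions wire the full pipeline together on synthetic corpora and are
what the repository's reproduction script executes.  Problem sizes are kept
small (tens of assays, ~100 generated molecules) so a study completes in
seconds on one CPU while still exercising every stage.
"""

from __future__ import annotations

import numpy as np

from .chem_pool import BASE_POOL, full_pool
from .context_builder import PromptMode, build_prompt
from .evaluation import (
    MockDockingScorer,
    PlantedDockingScorer,
    context_similarity,
    evaluate_target,
    high_affinity_fraction,
    improvement_over_baseline,
    score_with,
)
from .generation import generate_batch, optimize_against_anti_target, validity_rate
from .pipeline import PipelineResult, run_pipeline
from .providers import HashedTokenEmbedder, planted_identity_provider
from .retrieval_filter import RetrievalConfig
from .synthetic_corpus import (
    CorpusManifest,
    CorpusSpec,
    MockTextProvider,
    make_corpus,
    make_query,
    make_unrelated_query,
)


def _generation_backend(seed: int, bias: bool = True):
    """Factory for a pool-backed mock generator, biased toward context actives."""

    def factory(context):
        bias_molecules = context.context_actives if bias else None
        return MockTextProvider(
            pool=list(full_pool()),
            seed=seed,
            bias_molecules=bias_molecules or None,
        )

    return factory


def run_offline_pipeline(
    seed: int,
    family: int | None = 0,
    n_assays: int = 40,
    n_families: int = 2,
    n_molecules: int = 100,
    batch_size: int = 10,
    bias_generation: bool = True,
    config: RetrievalConfig | None = None,
) -> tuple[PipelineResult, CorpusManifest]:
    """One full mock run: corpus -> index -> retrieve -> context -> generate.

    ``family=None`` runs an unrelated query (the no-relevance arm).
    """
    spec = CorpusSpec(
        n_assays=n_assays,
        n_families=n_families,
        actives_fraction=0.35,
        table_size_range=(16, 30),
        counterscreen_fraction=0.15,
        seed=seed,
    )
    records, manifest = make_corpus(spec)
    config = config or RetrievalConfig(k=n_assays, seed=seed)
    query = make_query(manifest, family) if family is not None else make_unrelated_query()
    text_provider = MockTextProvider(manifest=manifest, query_family=family)
    result = run_pipeline(
        records,
        query,
        config,
        HashedTokenEmbedder(dim=64, seed=0),
        text_provider,
        _generation_backend(seed + 1, bias=bias_generation),
        n_molecules=n_molecules,
        batch_size=batch_size,
        identity_provider=planted_identity_provider(manifest.identity_table),
    )
    return result, manifest


def corrupted_validity(seed: int, n_batches: int = 10, batch_size: int = 10) -> float:
    """Validity rate over whole batches from a 10%-corrupted mock generator."""
    provider = MockTextProvider(pool=list(full_pool()), seed=seed, corrupt_every=10)
    prompt = (
        "Target description: corrupted-mock check.\n"
        f"generate {batch_size} new candidate molecules\n"
    )
    molecules = [
        m for i in range(n_batches) for m in generate_batch(prompt, provider, batch_size, i)
    ]
    return validity_rate(molecules)


def planted_improvements(seed: int, n_molecules: int = 30) -> tuple[float, float]:
    """Mean docking improvement for a high-relevance vs a no-relevance query.

    Both arms are scored by the same planted scorer, which rewards similarity
    to the high-relevance family's known actives, against the same baseline
    distribution (a fixed drug-like background set).  A pipeline that
    retrieves the right context and imitates its actives should show the
    larger improvement.
    """
    target = "planted-target"
    result_high, manifest = run_offline_pipeline(
        seed, family=0, n_assays=24, n_molecules=n_molecules
    )
    result_none, _ = run_offline_pipeline(
        seed, family=None, n_assays=24, n_molecules=n_molecules
    )
    scorer = PlantedDockingScorer(
        {target: manifest.family_active_pool[0]}, seed=seed, noise=0.3, effect=3.0
    )
    rng = np.random.default_rng(seed)
    baseline_pool = [str(s) for s in rng.choice(list(BASE_POOL), size=20, replace=False)]
    baseline = list(score_with(scorer, baseline_pool, target).values())

    def improvement(result: PipelineResult) -> float:
        scores = list(score_with(scorer, result.valid_smiles, target).values())
        return improvement_over_baseline(scores, baseline)

    return improvement(result_high), improvement(result_none)


def planted_effect_replicates(n_replicates: int = 20, seed: int = 0) -> dict:
    """Replicate the high-vs-none comparison across seeds; count wins."""
    highs, nones = [], []
    for i in range(n_replicates):
        high, none = planted_improvements(seed + 1000 * i, n_molecules=20)
        highs.append(high)
        nones.append(none)
    wins = sum(1 for h, n in zip(highs, nones) if h > n)
    return {
        "n_replicates": n_replicates,
        "wins": wins,
        "mean_improvement_high": float(np.mean(highs)),
        "mean_improvement_none": float(np.mean(nones)),
    }


def anti_target_optimization_study(seed: int, n_molecules: int = 10) -> dict:
    """Counterscreen-style optimization: rewrite molecules to shed anti-target affinity.

    An optimize-mode context is built for an anti-target family; generated
    molecules from a prior run are appended and a scripted mock rewrites each
    toward the drug-like base pool.  The planted scorer (anti-target = family
    actives) should score the rewritten molecules strictly worse (higher),
    i.e. affinity for the anti-target drops.
    """
    result, manifest = run_offline_pipeline(seed, family=0, n_assays=24, n_molecules=n_molecules)
    molecules = result.valid_smiles[:n_molecules]
    anti_context = build_prompt(
        make_query(manifest, 0),
        result.context.blocks,
        mode=PromptMode.OPTIMIZE_ANTI_TARGET,
        optimization_targets=molecules,
    )
    base = [str(s) for s in BASE_POOL]
    script = {m: base[i % len(base)] for i, m in enumerate(molecules)}
    provider = MockTextProvider(optimize_script=script)
    pairs = optimize_against_anti_target(molecules, anti_context, provider)
    anti_target = "anti-target"
    scorer = PlantedDockingScorer(
        {anti_target: manifest.family_active_pool[0]}, seed=seed, noise=0.2, effect=3.0
    )
    before = [scorer.score(m, anti_target) for m, _ in pairs]
    after = [scorer.score(opt.smiles, anti_target) for _, opt in pairs]
    return {
        "mean_score_before": float(np.mean(before)),
        "mean_score_after": float(np.mean(after)),
        "n_pairs": len(pairs),
    }


def offline_study(seed: int) -> dict:
    """The package's headline offline computation: one full evaluated run.

    Returns a flat dict of the quantities the pipeline produces on a seeded
    synthetic study; deterministic given the seed.
    """
    result, manifest = run_offline_pipeline(seed, family=0, n_molecules=100)
    target = "study-target"
    scorer = MockDockingScorer(seed=seed)
    scores = list(score_with(scorer, result.valid_smiles, target).values())
    rng = np.random.default_rng(seed)
    baseline_pool = [str(s) for s in rng.choice(list(BASE_POOL), size=20, replace=False)]
    baseline = list(score_with(scorer, baseline_pool, target).values())
    ref_score = float(np.median(baseline))
    report = evaluate_target(
        target,
        result.valid_smiles,
        scorer=scorer,
        ref_score=ref_score,
        baseline_scores=baseline,
        context_molecules=result.context.context_smiles,
        relevance_group=result.relevance_group,
    )
    unbiased = MockTextProvider(pool=list(full_pool()), seed=seed + 2)
    unbiased_mols = generate_batch(result.context.prompt, unbiased, 100)
    unbiased_sim = context_similarity(
        [m.smiles for m in unbiased_mols if m.valid], result.context.context_smiles
    )
    high, none = planted_improvements(seed, n_molecules=30)
    return {
        "n_generated": len(result.molecules),
        "validity_rate_clean": validity_rate(result.molecules),
        "validity_rate_corrupted": corrupted_validity(seed),
        "relevance_x": result.relevance_x,
        "relevance_group": result.relevance_group,
        "n_selected_assays": len(result.selected),
        "diversity": report.diversity,
        "qed_mean": report.metric_means()["qed"],
        "sa_norm_mean": report.metric_means()["sa_norm"],
        "size_mean": report.metric_means()["size"],
        "dock_score_mean": report.metric_means()["dock_score"],
        "high_affinity": report.high_affinity,
        "improvement_vs_baseline": report.improvement,
        "context_similarity_mean_biased": report.context_similarity_stats["mean"],
        "context_similarity_mean_unbiased": float(np.mean(unbiased_sim)),
        "improvement_high_relevance": high,
        "improvement_no_relevance": none,
    }
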