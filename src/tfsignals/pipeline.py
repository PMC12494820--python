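"""End-to-end orchestration: inputs -> activities -> correlations ->
thresholds -> distances -> candidate list.

One top-level seed drives activity-inference subsampling and the
bootstrap via spawned child seeds, so a full run is reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import infer_activities, ko_direction_benchmark, BenchmarkResult
from .bootstrap import (
    BootstrapResult,
    StabilityScores,
    bootstrap_correlations,
    median_roc_threshold,
    roc_for_sample,
    select_stability_threshold,
    stability_scores,
)
from .datamodel import (
    CandidatePair,
    ExpressionMatrix,
    KnownInteractionSet,
    MetabolicModel,
    MetaboliteAbundanceMatrix,
    RegulatoryNetwork,
    TFActivityMatrix,
)
from .distance import build_graph, distance_table
from .predict import (
    FilterConfig,
    PredictionSummary,
    filter_candidates,
    summarize_predictions,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    activities: TFActivityMatrix
    benchmark: BenchmarkResult
    bootstrap: BootstrapResult
    correlation_threshold: float
    median_roc: pd.DataFrame
    stability: StabilityScores
    stability_cutoff: float
    distances: pd.DataFrame
    candidates: list[CandidatePair]
    summary: PredictionSummary
    auc: float


def run_pipeline(
    expression: ExpressionMatrix,
    network: RegulatoryNetwork,
    metabolome: MetaboliteAbundanceMatrix,
    model: MetabolicModel,
    known: KnownInteractionSet,
    n_subnets: int = 10,
    extra_tfs: int = 40,
    n_samples: int = 1000,
    subsample_size: int | None = None,
    target_fpr: float = 0.1,
    distance_cutoff: float = 0,
    effect: str = "activating",
    hub_cutoff: int = 50,
    stability_cutoff: float | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full prediction pipeline on validated inputs.

    ``subsample_size`` defaults to 3/4 of the shared conditions (30 of
    40 in the reference design). ``stability_cutoff=None`` selects the
    cutoff that maximizes known-interaction retention.
    """
    seeds = np.random.SeedSequence(seed).spawn(2)
    act_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    boot_seed = int(seeds[1].generate_state(1)[0] % (2**31))

    activities = infer_activities(
        expression, network, n_subnets=n_subnets, extra_tfs=extra_tfs, seed=act_seed
    )
    benchmark = ko_direction_benchmark(activities, expression.condition_meta)

    shared = [c for c in activities.conditions if c in set(metabolome.conditions)]
    if subsample_size is None:
        subsample_size = max(3, (3 * len(shared)) // 4)
    boot = bootstrap_correlations(
        activities,
        metabolome,
        n_samples=n_samples,
        subsample_size=subsample_size,
        seed=boot_seed,
    )
    threshold, median_curve = median_roc_threshold(
        boot, known, effect=effect, target_fpr=target_fpr
    )
    auc = roc_for_sample(boot.mean_flat(), known, effect=effect).auc
    stab = stability_scores(boot, threshold, effect=effect)
    if stability_cutoff is None:
        stability_cutoff = select_stability_threshold(stab, known, effect=effect)

    graph = build_graph(model, network, hub_cutoff=hub_cutoff)
    distances = distance_table(
        graph,
        tfs=boot.tfs,
        metabolites=boot.metabolites,
        annotations=metabolome.annotations,
    )
    cfg = FilterConfig(
        target_fpr=target_fpr,
        stability_cutoff=stability_cutoff,
        distance_cutoff=distance_cutoff,
        effect=effect,
    )
    candidates = filter_candidates(boot, stab, distances, cfg, known=known)
    summary = summarize_predictions(candidates, known)
    return PipelineResult(
        activities=activities,
        benchmark=benchmark,
        bootstrap=boot,
        correlation_threshold=threshold,
        median_roc=median_curve,
        stability=stab,
        stability_cutoff=stability_cutoff,
        distances=distances,
        candidates=candidates,
        summary=summary,
        auc=auc,
    )
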