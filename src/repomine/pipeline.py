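"""End-to-end wiring: similarities -> mining -> cross-validation -> final model.

This is the standard composition of the library pieces; each stage
remains individually callable for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .classify import ClassifierSpec, EvaluationReport, cross_validate, train_classifier
from .data import AssociationIndex, FeatureTable
from .mining import MiningConfig, MiningReport, all_unknown_pairs, mine_negatives
from .scoring import build_design_matrix
from .similarity import FeatureSimilarities, build_all_similarities, get_text_backend

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level run configuration with the documented defaults."""

    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    mining: MiningConfig = field(default_factory=MiningConfig)
    text_backend: str = "hashing"
    mask_self: bool = True
    n_folds: int = 5
    seed: int = 0
    max_negatives_per_positive: float | None = None  # cap for huge grids; None = keep all


@dataclass
class PipelineResult:
    sims: FeatureSimilarities
    mining_report: MiningReport
    evaluation: EvaluationReport
    model: object
    dataset_pairs: list[tuple[str, str]]
    dataset_labels: list[int]

    @property
    def metrics(self) -> dict[str, float]:
        return self.evaluation.aggregate


def run_pipeline(
    drug_table: FeatureTable,
    disease_table: FeatureTable,
    index: AssociationIndex,
    config: PipelineConfig = PipelineConfig(),
    sims: FeatureSimilarities | None = None,
) -> PipelineResult:
    """Run the full procedure on one dataset.

    Builds per-feature similarity matrices, mines hard negatives from the
    unknown grid, evaluates the final classifier with stratified
    cross-validation on positives + mined negatives, and fits the final
    model on the whole labeled set (with the full-positive index) for
    candidate ranking.
    """
    if sims is None:
        backend = get_text_backend(config.text_backend)
        sims = build_all_similarities(drug_table, disease_table, backend=backend)

    positives = sorted(index.positives)
    unknowns = all_unknown_pairs(sims.drug_ids, sims.disease_ids, index)

    # the run seed governs every stage unless a stage carries its own
    classifier_spec = replace(config.classifier, seed=config.seed)
    mining_cfg = replace(config.mining, seed=config.seed)
    mining_index = AssociationIndex.from_pairs(positives)  # mining featurizes against train positives

    def mining_featurizer(pairs: list[tuple[str, str]]) -> pd.DataFrame:
        return build_design_matrix(pairs, sims, mining_train_index, mask_self=config.mask_self)

    # the mining-train index is fixed by the mining split; compute it here
    from .mining import split_positives

    train_pos, _ = split_positives(positives, mining_cfg.split_fraction, mining_cfg.seed)
    mining_train_index = mining_index.restrict(train_pos)

    mining_report = mine_negatives(positives, unknowns, mining_featurizer, mining_cfg)

    negatives = sorted(mining_report.selected_negatives)
    if config.max_negatives_per_positive is not None:
        cap = int(config.max_negatives_per_positive * len(positives))
        if len(negatives) > cap:
            import numpy as np

            rng = np.random.default_rng(config.seed)
            keep = rng.choice(len(negatives), size=cap, replace=False)
            negatives = sorted(negatives[i] for i in keep)

    pairs = positives + negatives
    labels = [1] * len(positives) + [0] * len(negatives)
    evaluation = cross_validate(
        pairs,
        labels,
        sims,
        classifier_spec,
        n_folds=config.n_folds,
        seed=config.seed,
        mask_self=config.mask_self,
    )

    X = build_design_matrix(pairs, sims, index, mask_self=config.mask_self)
    model = train_classifier(X.values, labels, classifier_spec)

    return PipelineResult(
        sims=sims,
        mining_report=mining_report,
        evaluation=evaluation,
        model=model,
        dataset_pairs=pairs,
        dataset_labels=labels,
    )
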