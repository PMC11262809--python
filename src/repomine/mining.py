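"""Hard negative mining over the unknown portion of the drug-disease grid.

Known associations are positive-unlabeled data: every pair outside the
positive list is merely *unknown*. Training negatives are selected in
three steps:

1. Split the positives once into a fixed train/test split (default
   80/20). Partition the unknown pairs into segments, each about the size
   of the positive set, and split each segment 80/20 the same way.
2. For each segment, train a base classifier on positive-train +
   segment-train (labels 1/0) and count, per unknown pair, how many of
   the segment models predict it positive. That count is the pair's
   ``num_pred`` vote, ranging from 0 to the number of segments.
3. Keep as negatives exactly the unknown pairs with ``num_pred = 0`` —
   the pairs no model ever mistook for a positive.

Voting scope matters because tree ensembles memorize their own training
rows: a model asked only about its own segment would never flip its
in-sample unknowns (labeled 0 during training) to positive, and pairs
that genuinely resemble positives would slip through on the train side
of the split. The default scope ``all`` therefore has every segment
model vote on every unknown pair, so each pair receives mostly
out-of-sample votes; scope ``segment`` restricts votes to the pair's own
segment (then num_pred is 0 or 1).

The default *disjoint* mode partitions the unknowns once. The
*resampled* mode repartitions them afresh for each of n_segments rounds
and counts votes per round within scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AssociationIndex

__all__ = [
    "MiningConfig",
    "MiningReport",
    "NoHardNegativesError",
    "split_positives",
    "segment_unknowns",
    "mine_negatives",
    "all_unknown_pairs",
]

Pair = tuple[str, str]


class NoHardNegativesError(RuntimeError):
    """Every unknown pair was voted positive at least once."""


@dataclass(frozen=True)
class MiningConfig:
    """Knobs of the mining procedure.

    n_segments "auto" sizes segments to the positive count; split_fraction
    is the share of positives (and of each segment) used for training.
    """

    n_segments: int | str = "auto"
    split_fraction: float = 0.8
    base_classifier: str | object = "random_forest"  # registry name or zero-arg factory
    classifier_params: dict = field(default_factory=dict)
    mode: str = "disjoint"  # or "resampled"
    vote_scope: str = "all"  # or "segment"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly between 0 and 1")
        if self.n_segments != "auto" and int(self.n_segments) < 1:
            raise ValueError("n_segments must be >= 1 or 'auto'")
        if self.mode not in ("disjoint", "resampled"):
            raise ValueError(f"unknown mining mode {self.mode!r}")
        if self.vote_scope not in ("all", "segment"):
            raise ValueError(f"unknown vote scope {self.vote_scope!r}")


@dataclass(frozen=True)
class MiningReport:
    """Vote counts and the selected hard-negative set."""

    num_pred: dict[Pair, int]
    selected_negatives: frozenset[Pair]
    segment_assignment: dict[Pair, int]
    n_segments: int
    train_positives: frozenset[Pair]
    test_positives: frozenset[Pair]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (d, s, self.segment_assignment[(d, s)], self.num_pred[(d, s)], int((d, s) in self.selected_negatives))
            for (d, s) in sorted(self.num_pred)
        ]
        return pd.DataFrame(rows, columns=["drug_id", "disease_id", "segment", "num_pred", "selected"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _split_sizes(n: int, fraction: float) -> int:
    """Training-part size: floor(n * fraction), clamped so both parts are non-empty."""
    n_train = math.floor(n * fraction)
    if n_train < 1 or n - n_train < 1:
        n_train = min(max(n_train, 1), n - 1)
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"cannot split {n} items into two non-empty parts")
    return n_train


def split_positives(positives, fraction: float, seed: int) -> tuple[list[Pair], list[Pair]]:
    """One fixed, reproducible train/test split of the positive pairs."""
    ordered = sorted(positives)
    if len(ordered) < 2:
        raise ValueError("need at least 2 positives to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ordered))
    n_train = _split_sizes(len(ordered), fraction)
    train = [ordered[i] for i in perm[:n_train]]
    test = [ordered[i] for i in perm[n_train:]]
    return train, test


def segment_unknowns(
    unknown_pairs,
    n_positives: int,
    seed: int,
    n_segments: int | str = "auto",
) -> dict[Pair, int]:
    """Shuffled sequential partition of the unknowns into segments.

    With "auto", segments hold ``n_positives`` pairs each (the last takes
    the remainder); with an explicit count, sizes are ceil(n/k) with a
    shorter last segment.
    """
    ordered = sorted(unknown_pairs)
    if not ordered:
        raise ValueError("no unknown pairs to segment")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ordered))
    if n_segments == "auto":
        chunk = max(int(n_positives), 1)
    else:
        chunk = math.ceil(len(ordered) / int(n_segments))
    assignment: dict[Pair, int] = {}
    for pos, i in enumerate(perm):
        assignment[ordered[i]] = pos // chunk
    return assignment


def all_unknown_pairs(drug_ids, disease_ids, index: AssociationIndex) -> list[Pair]:
    """The complement of the positives over the full drug x disease grid."""
    return [(d, s) for d in sorted(drug_ids) for s in sorted(disease_ids) if (d, s) not in index]


def _make_base_classifier(config: MiningConfig, seed: int):
    if callable(config.base_classifier):
        return config.base_classifier()
    from .classify import ClassifierSpec, make_classifier

    return make_classifier(ClassifierSpec(config.base_classifier, dict(config.classifier_params), seed=seed))


def _vote_pass(
    X: pd.DataFrame,
    row_of: dict[Pair, int],
    train_pos: list[Pair],
    test_pos: list[Pair],
    assignment: dict[Pair, int],
    config: MiningConfig,
    rng: np.random.Generator,
    num_pred: dict[Pair, int],
) -> None:
    n_segments = max(assignment.values()) + 1
    segments: list[list[Pair]] = [[] for _ in range(n_segments)]
    for pair, seg in assignment.items():
        segments[seg].append(pair)
    X_pos_train = X.values[[row_of[p] for p in train_pos]]
    all_unknowns = sorted(assignment)
    X_all_unknowns = X.values[[row_of[p] for p in all_unknowns]]
    for seg_pairs in segments:
        seg_pairs = sorted(seg_pairs)
        if len(seg_pairs) >= 2:
            perm = rng.permutation(len(seg_pairs))
            n_train = _split_sizes(len(seg_pairs), config.split_fraction)
            seg_train = [seg_pairs[i] for i in perm[:n_train]]
            seg_test = [seg_pairs[i] for i in perm[n_train:]]
        else:
            seg_train, seg_test = seg_pairs, []
        X_seg_train = X.values[[row_of[p] for p in seg_train]]
        X_train = np.vstack([X_pos_train, X_seg_train])
        y_train = np.concatenate([np.ones(len(train_pos)), np.zeros(len(seg_train))])
        model = _make_base_classifier(config, seed=config.seed)
        model.fit(X_train, y_train)
        if config.vote_scope == "all":
            vote_pairs, X_vote = all_unknowns, X_all_unknowns
        else:
            # votes restricted to the model's own segment, whichever side
            # of the 80/20 split the pair fell on
            vote_pairs = seg_train + seg_test
            X_vote = X.values[[row_of[p] for p in vote_pairs]]
        proba = model.predict_proba(X_vote)[:, 1]
        for pair, p in zip(vote_pairs, proba):
            if p >= 0.5:
                num_pred[pair] += 1


def mine_negatives(
    positives,
    unknowns,
    featurizer,
    config: MiningConfig = MiningConfig(),
) -> MiningReport:
    """Run the three-step mining procedure and return the vote report.

    ``featurizer`` maps a list of pairs to a design-matrix DataFrame; it
    must be bound to the association index built from the mining-train
    positives (see :mod:`repomine.pipeline` for the standard wiring).
    """
    positives = sorted(set(positives))
    unknowns = sorted(set(unknowns))
    overlap = set(positives) & set(unknowns)
    if overlap:
        raise ValueError(f"{len(overlap)} pairs appear as both positive and unknown")
    train_pos, test_pos = split_positives(positives, config.split_fraction, config.seed)

    X = featurizer(positives + unknowns)
    row_of = {pair: i for i, pair in enumerate(positives + unknowns)}

    rng = np.random.default_rng(config.seed)
    num_pred: dict[Pair, int] = {pair: 0 for pair in unknowns}

    if config.mode == "disjoint":
        assignment = segment_unknowns(unknowns, len(positives), config.seed, config.n_segments)
        _vote_pass(X, row_of, train_pos, test_pos, assignment, config, rng, num_pred)
    else:  # resampled: fresh partitions, num_pred ranges over [0, n_rounds]
        if config.n_segments == "auto":
            n_rounds = math.ceil(len(unknowns) / len(positives))
        else:
            n_rounds = int(config.n_segments)
        assignment = {}
        for r in range(n_rounds):
            round_assignment = segment_unknowns(unknowns, len(positives), config.seed + 1 + r, "auto")
            if r == 0:
                assignment = round_assignment
            _vote_pass(X, row_of, train_pos, test_pos, round_assignment, config, rng, num_pred)

    n_segments = max(assignment.values()) + 1
    selected = frozenset(pair for pair, votes in num_pred.items() if votes == 0)
    if not selected:
        raise NoHardNegativesError(
            "every unknown pair was predicted positive at least once; "
            "try a different base classifier or more segments"
        )
    return MiningReport(
        num_pred=num_pred,
        selected_negatives=selected,
        segment_assignment=assignment,
        n_segments=n_segments,
        train_positives=frozenset(train_pos),
        test_positives=frozenset(test_pos),
    )
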