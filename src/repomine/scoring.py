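"""Guilt-by-association score vectors for (drug, disease) pairs.

For a pair (d, s), the evidence sets are A_d (diseases known-associated
with d in the training data) and B_s (drugs known-associated with s).
Each disease feature q contributes

    x_q(d, s) = max over s' in A_d of sim_q(s, s')

and each drug feature p contributes

    x_p(d, s) = max over d' in B_s of sim_p(d, d').

The max (rather than mean or min) encodes that one strongly similar
neighbor is enough to suggest an association. The adjusted scores weight
each raw score by the size of the *opposite* evidence set:

    ax_p = |A_d| * x_p        ax_q = |B_s| * x_q

so features backed by many known associations are emphasized.
Concatenating x (k + l values), ax (k + l values), |A_d| and |B_s| gives
a vector of length 2j + 2 with j = k + l.

An empty evidence set scores 0 (a cold-start entity has no supporting
neighbor). With ``mask_self`` on — the default — a pair that is itself a
training positive is removed from its own evidence sets before scoring;
otherwise sim(s, s) = 1 makes every training positive trivially
separable and the learned model leaks its labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AssociationIndex, SimilarityMatrix
from .similarity import FeatureSimilarities

__all__ = [
    "score_x_q",
    "score_x_p",
    "adjust_scores",
    "PairFeatureVector",
    "assemble_pair_vector",
    "build_design_matrix",
]


def _max_sim(matrix: SimilarityMatrix, query: str, members) -> float:
    """max over members of sim(query, member); 0 for an empty member set."""
    if not members:
        return 0.0
    row = matrix.index_of(query)
    cols = [matrix.index_of(m) for m in members]
    return float(matrix.values[row, cols].max())


def score_x_q(d: str, s: str, sim_q: SimilarityMatrix, A_d) -> float:
    """Max similarity between disease s and the diseases associated with drug d."""
    return _max_sim(sim_q, s, A_d)


def score_x_p(d: str, s: str, sim_p: SimilarityMatrix, B_s) -> float:
    """Max similarity between drug d and the drugs associated with disease s."""
    return _max_sim(sim_p, d, B_s)


def adjust_scores(x_p: np.ndarray, x_q: np.ndarray, size_A: int, size_B: int):
    """Adjusted scores: drug-feature scores weighted by |A_d|, disease-feature scores by |B_s|."""
    return size_A * np.asarray(x_p, dtype=float), size_B * np.asarray(x_q, dtype=float)


@dataclass(frozen=True)
class PairFeatureVector:
    """The 2j+2 score vector for one (drug, disease) pair."""

    drug_id: str
    disease_id: str
    x_p: np.ndarray  # k raw drug-feature scores
    x_q: np.ndarray  # l raw disease-feature scores
    ax_p: np.ndarray
    ax_q: np.ndarray
    size_A: int
    size_B: int
    slot_names: tuple[str, ...]

    def to_array(self) -> np.ndarray:
        return np.concatenate(
            [self.x_p, self.x_q, self.ax_p, self.ax_q, [float(self.size_A)], [float(self.size_B)]]
        )

    def __len__(self) -> int:
        return len(self.slot_names)


def _masked_sets(index: AssociationIndex, d: str, s: str, mask_self: bool):
    A_d = index.diseases_of(d)
    B_s = index.drugs_of(s)
    if mask_self and (d, s) in index:
        A_d = A_d - {s}
        B_s = B_s - {d}
    return A_d, B_s


def assemble_pair_vector(
    d: str,
    s: str,
    sims: FeatureSimilarities,
    index: AssociationIndex,
    mask_self: bool = True,
) -> PairFeatureVector:
    """Score one pair against every feature matrix, in fixed slot order."""
    catalog = sims.catalog
    A_d, B_s = _masked_sets(index, d, s, mask_self)
    x_p = np.array([score_x_p(d, s, sims.drug[p.name], B_s) for p in catalog.drug_features])
    x_q = np.array([score_x_q(d, s, sims.disease[q.name], A_d) for q in catalog.disease_features])
    ax_p, ax_q = adjust_scores(x_p, x_q, len(A_d), len(B_s))
    return PairFeatureVector(
        drug_id=d,
        disease_id=s,
        x_p=x_p,
        x_q=x_q,
        ax_p=ax_p,
        ax_q=ax_q,
        size_A=len(A_d),
        size_B=len(B_s),
        slot_names=tuple(catalog.slot_names()),
    )


def build_design_matrix(
    pairs,
    sims: FeatureSimilarities,
    index: AssociationIndex,
    mask_self: bool = True,
) -> pd.DataFrame:
    """One score-vector row per pair, with stable named columns.

    Equivalent to row-by-row :func:`assemble_pair_vector`, but vectorized:
    pairs are grouped by drug (for disease-feature scores, which share
    A_d) and by disease (for drug-feature scores, which share B_s), and
    each group is scored with one sub-matrix max. Pairs that are training
    positives are re-scored individually with themselves masked out.
    """
    pairs = [(str(d), str(s)) for d, s in pairs]
    catalog = sims.catalog
    k, l = catalog.k, catalog.l
    n = len(pairs)
    X = np.zeros((n, catalog.n_slots))
    slot = catalog.slot_names()

    masked = np.array([mask_self and p in index for p in pairs], dtype=bool)

    # evidence-set sizes (post-masking)
    size_A = np.array([len(index.diseases_of(d)) - int(m) for (d, _), m in zip(pairs, masked)], dtype=float)
    size_B = np.array([len(index.drugs_of(s)) - int(m) for (_, s), m in zip(pairs, masked)], dtype=float)

    by_drug: dict[str, list[int]] = {}
    by_disease: dict[str, list[int]] = {}
    for i, (d, s) in enumerate(pairs):
        by_drug.setdefault(d, []).append(i)
        by_disease.setdefault(s, []).append(i)

    # disease-feature scores x_q: one block per drug (shared A_d)
    for qi, spec in enumerate(catalog.disease_features):
        mat = sims.disease[spec.name]
        col = np.zeros(n)
        for d, idxs in by_drug.items():
            members = index.diseases_of(d)
            if members:
                rows = [mat.index_of(pairs[i][1]) for i in idxs]
                cols = [mat.index_of(m) for m in sorted(members)]
                col[idxs] = mat.values[np.ix_(rows, cols)].max(axis=1)
        for i in np.flatnonzero(masked):
            d, s = pairs[i]
            col[i] = score_x_q(d, s, mat, index.diseases_of(d) - {s})
        X[:, k + qi] = col

    # drug-feature scores x_p: one block per disease (shared B_s)
    for pi, spec in enumerate(catalog.drug_features):
        mat = sims.drug[spec.name]
        col = np.zeros(n)
        for s, idxs in by_disease.items():
            members = index.drugs_of(s)
            if members:
                rows = [mat.index_of(pairs[i][0]) for i in idxs]
                cols = [mat.index_of(m) for m in sorted(members)]
                col[idxs] = mat.values[np.ix_(rows, cols)].max(axis=1)
        for i in np.flatnonzero(masked):
            d, s = pairs[i]
            col[i] = score_x_p(d, s, mat, index.drugs_of(s) - {d})
        X[:, pi] = col

    X[:, k + l : 2 * k + l] = X[:, :k] * size_A[:, None]
    X[:, 2 * k + l : 2 * (k + l)] = X[:, k : k + l] * size_B[:, None]
    X[:, -2] = size_A
    X[:, -1] = size_B

    frame = pd.DataFrame(X, columns=slot)
    frame.index = pd.MultiIndex.from_tuples(pairs, names=["drug_id", "disease_id"])
    return frame
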