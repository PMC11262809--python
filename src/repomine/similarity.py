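"""Per-feature similarity matrices.

Set-valued features (categories, targets, tokenized SMILES, pathway and
slim-mapping annotations) are compared with Jaccard similarity,
|intersection| / |union|. Text features (descriptions, mechanism of
action, pharmacodynamics) are embedded once per entity and compared with
cosine similarity; the embedding backend is pluggable, with a
deterministic token-hashing vectorizer as the default so the whole
pipeline is reproducible without any language model.

Conventions: two empty sets score 0 (the 0/0 case carries no evidence);
an entity whose feature value is absent scores 0 against everything,
including itself. Negative cosines are floored at 0 so every matrix
shares the [0, 1] range that downstream max-scoring assumes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import HashingVectorizer

from .data import (
    FeatureCatalog,
    FeatureSpec,
    FeatureTable,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "jaccard_similarity",
    "cosine_similarity",
    "EmbeddingBackend",
    "HashingTextBackend",
    "get_text_backend",
    "register_text_backend",
    "build_set_similarity_matrix",
    "build_text_similarity_matrix",
    "build_all_similarities",
    "FeatureSimilarities",
    "load_similarity_matrix",
]


def jaccard_similarity(set_a, set_b) -> float:
    """Jaccard similarity |a ∩ b| / |a ∪ b| of two token sets.

    Both-empty returns 0: empty annotations carry no evidence of
    similarity, and 0 is neutral under the downstream max-aggregation.
    """
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors, clipped to [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


class EmbeddingBackend(Protocol):
    """Text embedding contract: deterministic, fixed dimension, non-zero on non-empty text."""

    name: str

    def embed(self, text: str) -> np.ndarray: ...


class HashingTextBackend:
    """Deterministic bag-of-tokens embedding via feature hashing.

    Tokens are hashed into a fixed number of buckets with non-negative
    counts (no sign alternation), so cosine similarities are naturally in
    [0, 1] and identical across runs and platforms. This is a
    language-model-free backend: it captures token overlap, not semantics.
    """

    def __init__(self, n_features: int = 512) -> None:
        self.name = f"hashing-{n_features}"
        self.n_features = n_features
        self._vectorizer = HashingVectorizer(
            n_features=n_features,
            alternate_sign=False,
            norm=None,
            token_pattern=r"(?u)\S+",
        )

    def embed(self, text: str) -> np.ndarray:
        vec = self._vectorizer.transform([text]).toarray().ravel()
        return vec.astype(float)


_TEXT_BACKENDS: dict[str, Callable[[], EmbeddingBackend]] = {
    "hashing": HashingTextBackend,
}


def register_text_backend(name: str, factory: Callable[[], EmbeddingBackend]) -> None:
    """Register an alternative embedding backend (e.g. a transformer plugin)."""
    _TEXT_BACKENDS[name] = factory


def get_text_backend(name: str = "hashing") -> EmbeddingBackend:
    if name.startswith("plugin:"):
        name = name.split(":", 1)[1]
    try:
        return _TEXT_BACKENDS[name]()
    except KeyError:
        raise KeyError(f"unknown text backend {name!r}; registered: {sorted(_TEXT_BACKENDS)}") from None


def _entity_universe(table: FeatureTable, entity_ids) -> list[str]:
    return sorted(entity_ids) if entity_ids is not None else table.entities()


def build_set_similarity_matrix(
    table: FeatureTable,
    feature: FeatureSpec | str,
    entity_ids=None,
) -> SimilarityMatrix:
    """Pairwise Jaccard matrix for one set-valued feature.

    Entities with an absent value get a zero row and column (diagonal
    included); entities with a present non-empty set get diagonal 1.
    """
    if isinstance(feature, str):
        feature = table.catalog.get(table.entity_class, feature)
    if feature.kind != "set_valued":
        raise ValidationError(f"feature {feature.name!r} is not set-valued")
    ids = _entity_universe(table, entity_ids)
    values = [table.get(e, feature.name) for e in ids]
    n = len(ids)
    mat = np.zeros((n, n))
    present = [i for i, v in enumerate(values) if v is not None]
    for ai, i in enumerate(present):
        for j in present[ai:]:
            s = jaccard_similarity(values[i], values[j])
            mat[i, j] = mat[j, i] = s
    return SimilarityMatrix(feature.name, ids, mat).validate()


def build_text_similarity_matrix(
    table: FeatureTable,
    feature: FeatureSpec | str,
    backend: EmbeddingBackend | None = None,
    entity_ids=None,
) -> SimilarityMatrix:
    """Pairwise cosine-of-embedding matrix for one text feature.

    Each text is embedded exactly once. Absent or empty texts behave like
    absent sets: similarity 0 to everything. Negative cosines (possible
    with signed backends) are floored at 0.
    """
    if isinstance(feature, str):
        feature = table.catalog.get(table.entity_class, feature)
    if feature.kind != "text":
        raise ValidationError(f"feature {feature.name!r} is not a text feature")
    backend = backend or get_text_backend()
    ids = _entity_universe(table, entity_ids)
    n = len(ids)
    embeddings: dict[int, np.ndarray] = {}
    for i, e in enumerate(ids):
        text = table.get(e, feature.name)
        if text is None or not str(text).strip():
            continue
        try:
            vec = np.asarray(backend.embed(str(text)), dtype=float).ravel()
        except Exception as exc:
            raise RuntimeError(f"embedding backend {backend.name!r} failed on entity {e!r}: {exc}") from exc
        if np.linalg.norm(vec) == 0.0:
            raise RuntimeError(f"embedding backend {backend.name!r} returned a zero vector for entity {e!r}")
        embeddings[i] = vec
    mat = np.zeros((n, n))
    present = sorted(embeddings)
    for ai, i in enumerate(present):
        for j in present[ai:]:
            s = max(cosine_similarity(embeddings[i], embeddings[j]), 0.0)
            mat[i, j] = mat[j, i] = s
    # guard against fp drift just above 1 on the diagonal
    np.clip(mat, 0.0, 1.0, out=mat)
    return SimilarityMatrix(feature.name, ids, mat).validate()


class FeatureSimilarities:
    """All per-feature similarity matrices for one catalog, keyed by class and name."""

    def __init__(
        self,
        catalog: FeatureCatalog,
        drug: dict[str, SimilarityMatrix],
        disease: dict[str, SimilarityMatrix],
    ) -> None:
        for spec in catalog.drug_features:
            if spec.name not in drug:
                raise ValidationError(f"missing drug similarity matrix for feature {spec.name!r}")
        for spec in catalog.disease_features:
            if spec.name not in disease:
                raise ValidationError(f"missing disease similarity matrix for feature {spec.name!r}")
        self.catalog = catalog
        self.drug = drug
        self.disease = disease

    def matrix(self, entity_class: str, feature_name: str) -> SimilarityMatrix:
        pool = self.drug if entity_class == "drug" else self.disease
        return pool[feature_name]

    @property
    def drug_ids(self) -> list[str]:
        return next(iter(self.drug.values())).entity_ids

    @property
    def disease_ids(self) -> list[str]:
        return next(iter(self.disease.values())).entity_ids


def _cache_key(table: FeatureTable, feature: FeatureSpec, backend_name: str) -> str:
    payload = {
        "feature": feature.name,
        "kind": feature.kind,
        "backend": backend_name,
        "values": sorted(
            (e, feature.name, sorted(v) if isinstance(v, frozenset) else v)
            for (e, f), v in table._values.items()
            if f == feature.name
        ),
        "entities": table.entities(),
    }
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
    return f"{feature.entity_class}__{feature.name}__{digest}"


def build_all_similarities(
    drug_table: FeatureTable,
    disease_table: FeatureTable,
    backend: EmbeddingBackend | None = None,
    drug_ids=None,
    disease_ids=None,
    cache_dir: str | Path | None = None,
) -> FeatureSimilarities:
    """Build every per-feature matrix declared in the catalog.

    With ``cache_dir`` set, matrices are cached to TSV keyed by feature,
    backend and a content hash; text embedding is the costliest stage, so
    re-runs on unchanged inputs are near-free.
    """
    catalog = drug_table.catalog
    backend = backend or get_text_backend()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    def build(table: FeatureTable, spec: FeatureSpec, ids) -> SimilarityMatrix:
        backend_name = backend.name if spec.kind == "text" else "jaccard"
        if cache is not None:
            path = cache / f"{_cache_key(table, spec, backend_name)}.tsv"
            if path.exists():
                mat = load_similarity_matrix(path, feature_name=spec.name)
                if mat.entity_ids == _entity_universe(table, ids):
                    return mat
        if spec.kind == "set_valued":
            mat = build_set_similarity_matrix(table, spec, entity_ids=ids)
        else:
            mat = build_text_similarity_matrix(table, spec, backend=backend, entity_ids=ids)
        if cache is not None:
            mat.write(path)
        return mat

    drug = {spec.name: build(drug_table, spec, drug_ids) for spec in catalog.drug_features}
    disease = {spec.name: build(disease_table, spec, disease_ids) for spec in catalog.disease_features}
    return FeatureSimilarities(catalog, drug, disease)


def load_similarity_matrix(path: str | Path, feature_name: str | None = None) -> SimilarityMatrix:
    """Load and validate a square TSV similarity matrix.

    The header row and first column must carry matching entity ids;
    asymmetry beyond 1e-8 or entries outside [0, 1] are rejected. This is
    also the entry point for externally computed matrices (e.g. phenotype
    similarity used in place of disease feature tables).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids_row = [str(c) for c in df.columns]
    ids_col = [str(i) for i in df.index]
    if ids_row != ids_col:
        raise ValidationError(f"{path}: header ids and first-column ids differ")
    name = feature_name if feature_name is not None else Path(path).stem
    return SimilarityMatrix(name, ids_row, df.to_numpy(dtype=float)).validate()
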