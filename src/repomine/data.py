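"""Domain types and TSV readers/writers for the repositioning pipeline.

Entities are drugs and diseases identified by short string ids. Each entity
class carries an ordered catalog of features; a feature is either
*set-valued* (a finite token set, e.g. therapeutic categories or tokenized
SMILES) or *text* (a free-text description embedded downstream). Known
drug-disease associations are stored as a bipartite index with both
adjacency directions materialized.

All on-disk formats are tab-separated UTF-8 with a header row. Set-valued
cells are pipe-delimited token lists (``a|b|c``) so that commas inside
condition names stay unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "FeatureCatalog",
    "FeatureTable",
    "AssociationIndex",
    "SimilarityMatrix",
    "PredictionRecord",
    "ParseError",
    "ValidationError",
    "read_feature_table",
    "read_associations",
    "write_associations",
    "write_predictions",
]

EntityClass = Literal["drug", "disease"]
FeatureKind = Literal["set_valued", "text"]

SET_DELIMITER = "|"


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


def _check_entity_id(entity_id: str) -> str:
    if not entity_id or any(ch.isspace() for ch in entity_id):
        raise ValidationError(f"invalid entity id {entity_id!r}: must be a non-empty token without whitespace")
    return entity_id


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one feature: its name, entity class, and kind."""

    name: str
    entity_class: EntityClass
    kind: FeatureKind

    def __post_init__(self) -> None:
        if self.entity_class not in ("drug", "disease"):
            raise ValidationError(f"unknown entity class {self.entity_class!r}")
        if self.kind not in ("set_valued", "text"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature declarations for both entity classes.

    The order is load-bearing: it fixes the slot order of every pair
    feature vector, so feature importances and serialized models stay
    comparable across runs.
    """

    drug_features: tuple[FeatureSpec, ...]
    disease_features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_features", tuple(self.drug_features))
        object.__setattr__(self, "disease_features", tuple(self.disease_features))
        if not self.drug_features or not self.disease_features:
            raise ValidationError("catalog needs at least one feature per entity class")
        for specs, cls in ((self.drug_features, "drug"), (self.disease_features, "disease")):
            names = [s.name for s in specs]
            if len(set(names)) != len(names):
                raise ValidationError(f"duplicate {cls} feature names: {names}")
            for s in specs:
                if s.entity_class != cls:
                    raise ValidationError(f"feature {s.name!r} has class {s.entity_class}, expected {cls}")

    @property
    def k(self) -> int:
        return len(self.drug_features)

    @property
    def l(self) -> int:
        return len(self.disease_features)

    @property
    def j(self) -> int:
        return self.k + self.l

    @property
    def n_slots(self) -> int:
        """Length of the pair feature vector: 2j + 2."""
        return 2 * self.j + 2

    def features(self, entity_class: EntityClass) -> tuple[FeatureSpec, ...]:
        return self.drug_features if entity_class == "drug" else self.disease_features

    def get(self, entity_class: EntityClass, name: str) -> FeatureSpec:
        for spec in self.features(entity_class):
            if spec.name == name:
                return spec
        raise KeyError(f"no {entity_class} feature named {name!r}")

    def slot_names(self) -> list[str]:
        """Column names of the 2j+2 pair vector, in fixed slot order.

        Order: raw max-similarity scores (drug features then disease
        features), adjusted scores in the same order, then the two
        evidence-set sizes.
        """
        names = [f"x__drug__{s.name}" for s in self.drug_features]
        names += [f"x__disease__{s.name}" for s in self.disease_features]
        names += [f"ax__drug__{s.name}" for s in self.drug_features]
        names += [f"ax__disease__{s.name}" for s in self.disease_features]
        names += ["size_A", "size_B"]
        return names


class FeatureTable:
    """Feature values for one entity class, keyed by (entity_id, feature_name).

    A missing (entity, feature) combination is *absent* — distinct from an
    empty set. Absent values yield similarity 0 against every other entity
    for that feature.
    """

    def __init__(self, catalog: FeatureCatalog, entity_class: EntityClass) -> None:
        self.catalog = catalog
        self.entity_class: EntityClass = entity_class
        self._values: dict[tuple[str, str], frozenset[str] | str] = {}
        self._entities: set[str] = set()

    def set_value(self, entity_id: str, feature_name: str, value: Iterable[str] | str) -> None:
        spec = self.catalog.get(self.entity_class, feature_name)
        _check_entity_id(entity_id)
        if spec.kind == "set_valued":
            if isinstance(value, str):
                raise ValidationError(f"feature {feature_name!r} is set-valued; got a bare string")
            value = frozenset(value)
        else:
            if not isinstance(value, str):
                raise ValidationError(f"feature {feature_name!r} is text; got {type(value).__name__}")
        key = (entity_id, feature_name)
        if key in self._values:
            if spec.kind == "set_valued":
                value = self._values[key] | value  # type: ignore[operator]
            else:
                raise ValidationError(f"duplicate text value for entity {entity_id!r}, feature {feature_name!r}")
        self._values[key] = value
        self._entities.add(entity_id)

    def add_entity(self, entity_id: str) -> None:
        """Register an entity even if it has no feature values."""
        self._entities.add(_check_entity_id(entity_id))

    def get(self, entity_id: str, feature_name: str) -> frozenset[str] | str | None:
        """Return the value, or None when absent."""
        return self._values.get((entity_id, feature_name))

    def entities(self) -> list[str]:
        return sorted(self._entities)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.entity_class == other.entity_class
            and self._values == other._values
            and self._entities == other._entities
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with set values rendered as sorted pipe-joined strings."""
        rows = []
        for (entity_id, feature_name), value in sorted(self._values.items()):
            if isinstance(value, frozenset):
                rendered = SET_DELIMITER.join(sorted(value))
            else:
                rendered = value
            rows.append((entity_id, feature_name, rendered))
        return pd.DataFrame(rows, columns=["entity_id", "feature_name", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path, catalog: FeatureCatalog, entity_class: EntityClass) -> FeatureTable:
    """Read a long-format TSV of (entity_id, feature_name, value) rows.

    Set-valued cells are split on ``|``; duplicate set-valued rows merge by
    union, duplicate text rows raise. Unknown feature names are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"entity_id", "feature_name", "value"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    table = FeatureTable(catalog, entity_class)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        entity_id, feature_name, raw = row.entity_id, row.feature_name, row.value
        if not entity_id or not feature_name:
            raise ParseError(f"{path}:{i}: empty entity_id or feature_name")
        try:
            spec = catalog.get(entity_class, feature_name)
        except KeyError as exc:
            raise ParseError(f"{path}:{i}: {exc.args[0]}") from exc
        try:
            if spec.kind == "set_valued":
                tokens = [t for t in raw.split(SET_DELIMITER) if t]
                table.set_value(entity_id, feature_name, tokens)
            else:
                table.set_value(entity_id, feature_name, raw)
        except ValidationError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    return table


@dataclass(frozen=True)
class AssociationIndex:
    """Known positive (drug, disease) pairs with both adjacency directions.

    ``A[d]`` is the set of diseases associated with drug ``d``; ``B[s]`` the
    set of drugs associated with disease ``s``. The two maps are exact
    transposes of each other by construction.
    """

    positives: frozenset[tuple[str, str]]
    A: Mapping[str, frozenset[str]] = field(compare=False)
    B: Mapping[str, frozenset[str]] = field(compare=False)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationIndex":
        positives = frozenset((str(d), str(s)) for d, s in pairs)
        a: dict[str, set[str]] = {}
        b: dict[str, set[str]] = {}
        for d, s in positives:
            _check_entity_id(d)
            _check_entity_id(s)
            a.setdefault(d, set()).add(s)
            b.setdefault(s, set()).add(d)
        return cls(
            positives=positives,
            A={d: frozenset(v) for d, v in a.items()},
            B={s: frozenset(v) for s, v in b.items()},
        )

    def diseases_of(self, drug_id: str) -> frozenset[str]:
        return self.A.get(drug_id, frozenset())

    def drugs_of(self, disease_id: str) -> frozenset[str]:
        return self.B.get(disease_id, frozenset())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.positives

    def __len__(self) -> int:
        return len(self.positives)

    def restrict(self, pairs: Iterable[tuple[str, str]]) -> "AssociationIndex":
        """Index over the subset of positives appearing in ``pairs``."""
        keep = set(pairs)
        return AssociationIndex.from_pairs(p for p in self.positives if p in keep)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.positives)
        return pd.DataFrame(rows, columns=["drug_id", "disease_id"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_associations(path: str | Path) -> AssociationIndex:
    """Read a TSV association list with drug_id and disease_id columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("drug_id", "disease_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return AssociationIndex.from_pairs(zip(df["drug_id"], df["disease_id"]))


def write_associations(index: AssociationIndex, path: str | Path) -> None:
    index.write(path)


@dataclass
class SimilarityMatrix:
    """Symmetric per-feature entity similarity matrix with values in [0, 1]."""

    feature_name: str
    entity_ids: list[str]
    values: np.ndarray

    _SYMMETRY_TOL = 1e-8

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.values = np.asarray(self.values, dtype=float)
        self._index = {e: i for i, e in enumerate(self.entity_ids)}
        if len(self._index) != len(self.entity_ids):
            raise ValidationError(f"{self.feature_name}: duplicate entity ids")
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"{self.feature_name}: matrix shape {self.values.shape} != ({n}, {n})")

    def validate(self) -> "SimilarityMatrix":
        if self.values.size:
            if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1 or np.isnan(self.values).any():
                raise ValidationError(f"{self.feature_name}: entries must lie in [0, 1]")
            if not np.allclose(self.values, self.values.T, atol=self._SYMMETRY_TOL, rtol=0):
                raise ValidationError(f"{self.feature_name}: matrix is not symmetric")
        return self

    def index_of(self, entity_id: str) -> int:
        try:
            return self._index[entity_id]
        except KeyError:
            raise KeyError(
                f"entity {entity_id!r} not present in similarity matrix for feature {self.feature_name!r}"
            ) from None

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="entity_id", float_format="%.10g")


@dataclass(frozen=True)
class PredictionRecord:
    """One scored (drug, disease) pair; label is 0, 1 or 'unknown'."""

    drug_id: str
    disease_id: str
    score: float
    label: int | str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1]")


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write predictions sorted by descending score, ties broken by ids."""
    ordered = sorted(records, key=lambda r: (-r.score, r.drug_id, r.disease_id))
    df = pd.DataFrame(
        [(r.drug_id, r.disease_id, r.score, r.label) for r in ordered],
        columns=["drug_id", "disease_id", "score", "label"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
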