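"""Self-contained synthetic drug-disease benchmarks with planted structure.

The generator emulates the shape of curated repositioning data — drugs
and diseases with set-valued and text features plus a known-association
list — with a block model that makes the similarity signal controllable:

* entities are assigned uniformly to clusters; each drug cluster is
  coupled to one disease cluster;
* set-valued features give same-cluster entities a shared token
  signature (each signature token kept with probability
  ``within_cluster_token_overlap``) plus background noise tokens, so
  same-cluster Jaccard similarity exceeds cross-cluster similarity in
  expectation;
* text features are token streams drawn mostly from a cluster-specific
  sub-vocabulary — the hashing embedding treats them exactly like real
  text;
* each positive association falls inside a matched (drug-cluster,
  disease-cluster) block with probability ``signal_strength`` and is
  uniform otherwise, so ``signal_strength=0`` is an exact null;
* a fraction of within-block candidate pairs is withheld as held-out
  truths, disjoint from the listed positives, for ranking checks.

Defaults are desk-scale (60 drugs x 40 diseases, ~96 positives) and use
the same 7-drug-feature / 3-disease-feature shape as curated sources
(category, condition, target and tokenized SMILES sets; description,
mechanism-of-action and pharmacodynamics texts; disease pathway and
slim-mapping sets plus a description text), so the default pair vector
has 2(7+3)+2 = 22 slots.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data import AssociationIndex, FeatureCatalog, FeatureSpec, FeatureTable

__all__ = ["GeneratorConfig", "SyntheticDataset", "default_catalog", "generate", "write_fixture"]

_DRUG_SET_NAMES = ["category", "condition", "target", "smiles_tokens"]
_DRUG_TEXT_NAMES = ["description", "mechanism_of_action", "pharmacodynamics"]
_DISEASE_SET_NAMES = ["pathway", "slim_mapping"]
_DISEASE_TEXT_NAMES = ["description"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the block-model generator; defaults are the study conditions.

    signal_strength is the probability that a positive association
    respects the planted cluster coupling (0 = pure noise, 1 = fully
    structured); density is the fraction of the drug x disease grid that
    is listed positive.
    """

    n_drugs: int = 60
    m_diseases: int = 40
    n_drug_clusters: int = 4
    n_disease_clusters: int = 3
    k_set_features_drug: int = 4
    k_text_features_drug: int = 3
    k_set_features_disease: int = 2
    k_text_features_disease: int = 1
    token_vocab_size: int = 400
    signature_size: int = 10
    background_tokens: int = 3
    text_length: int = 30
    text_subvocab_size: int = 25
    within_cluster_token_overlap: float = 0.75
    signal_strength: float = 0.9
    density: float = 0.04
    heldout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "m_diseases", "n_drug_clusters", "n_disease_clusters", "token_vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.k_set_features_drug + self.k_text_features_drug < 1:
            raise ValueError("need at least one drug feature")
        if self.k_set_features_disease + self.k_text_features_disease < 1:
            raise ValueError("need at least one disease feature")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0.0 <= self.within_cluster_token_overlap <= 1.0:
            raise ValueError("within_cluster_token_overlap must lie in [0, 1]")
        n_cells = self.n_drugs * self.m_diseases
        if not 0.0 < self.density < 0.5:
            raise ValueError("density must lie in (0, 0.5) so that unknown pairs exist")
        if round(n_cells * self.density) < 2:
            raise ValueError("density too low: fewer than 2 positives")


def _feature_names(canonical: list[str], prefix: str, count: int) -> list[str]:
    names = list(canonical[:count])
    names += [f"{prefix}_{i}" for i in range(len(names), count)]
    return names


def default_catalog(config: GeneratorConfig = GeneratorConfig()) -> FeatureCatalog:
    """Catalog implied by the generator config, set features first."""
    drug = [
        FeatureSpec(n, "drug", "set_valued")
        for n in _feature_names(_DRUG_SET_NAMES, "drug_set", config.k_set_features_drug)
    ] + [
        FeatureSpec(n, "drug", "text")
        for n in _feature_names(_DRUG_TEXT_NAMES, "drug_text", config.k_text_features_drug)
    ]
    disease = [
        FeatureSpec(n, "disease", "set_valued")
        for n in _feature_names(_DISEASE_SET_NAMES, "disease_set", config.k_set_features_disease)
    ] + [
        FeatureSpec(n, "disease", "text")
        for n in _feature_names(_DISEASE_TEXT_NAMES, "disease_text", config.k_text_features_disease)
    ]
    return FeatureCatalog(tuple(drug), tuple(disease))


@dataclass
class SyntheticDataset:
    """A generated benchmark: feature tables, associations, and ground truth."""

    config: GeneratorConfig
    catalog: FeatureCatalog
    drug_table: FeatureTable
    disease_table: FeatureTable
    index: AssociationIndex
    drug_clusters: dict[str, int]
    disease_clusters: dict[str, int]
    heldout_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.drug_clusters)

    @property
    def disease_ids(self) -> list[str]:
        return sorted(self.disease_clusters)

    def matched_block(self, drug_id: str, disease_id: str) -> bool:
        """True when the pair lies in a coupled (drug-cluster, disease-cluster) block."""
        g = self.drug_clusters[drug_id]
        h = self.disease_clusters[disease_id]
        return h == g % self.config.n_disease_clusters


def _fill_set_features(
    table: FeatureTable,
    ids: list[str],
    clusters: dict[str, int],
    n_clusters: int,
    feature_names: list[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    vocab = config.token_vocab_size
    for name in feature_names:
        signatures = [
            rng.choice(vocab, size=min(config.signature_size, vocab), replace=False)
            for _ in range(n_clusters)
        ]
        for e in ids:
            sig = signatures[clusters[e]]
            keep = sig[rng.random(len(sig)) < config.within_cluster_token_overlap]
            noise = rng.integers(0, vocab, size=config.background_tokens)
            tokens = {f"t{t}" for t in np.concatenate([keep, noise])}
            table.set_value(e, name, tokens)


def _fill_text_features(
    table: FeatureTable,
    ids: list[str],
    clusters: dict[str, int],
    n_clusters: int,
    feature_names: list[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    vocab = config.token_vocab_size
    for name in feature_names:
        subvocabs = [
            rng.choice(vocab, size=min(config.text_subvocab_size, vocab), replace=False)
            for _ in range(n_clusters)
        ]
        for e in ids:
            sub = subvocabs[clusters[e]]
            from_cluster = rng.random(config.text_length) < config.within_cluster_token_overlap
            words = np.where(
                from_cluster,
                rng.choice(sub, size=config.text_length),
                rng.integers(0, vocab, size=config.text_length),
            )
            table.set_value(e, name, " ".join(f"w{w}" for w in words))


def generate(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Draw one reproducible synthetic benchmark from the block model."""
    rng = np.random.default_rng(config.seed)
    catalog = default_catalog(config)

    width = max(3, len(str(config.n_drugs)))
    drug_ids = [f"D{i:0{width}d}" for i in range(1, config.n_drugs + 1)]
    disease_ids = [f"S{i:0{width}d}" for i in range(1, config.m_diseases + 1)]
    drug_clusters = {d: int(c) for d, c in zip(drug_ids, rng.integers(0, config.n_drug_clusters, config.n_drugs))}
    disease_clusters = {
        s: int(c) for s, c in zip(disease_ids, rng.integers(0, config.n_disease_clusters, config.m_diseases))
    }

    drug_table = FeatureTable(catalog, "drug")
    disease_table = FeatureTable(catalog, "disease")
    for e in drug_ids:
        drug_table.add_entity(e)
    for e in disease_ids:
        disease_table.add_entity(e)
    drug_set = [s.name for s in catalog.drug_features if s.kind == "set_valued"]
    drug_text = [s.name for s in catalog.drug_features if s.kind == "text"]
    disease_set = [s.name for s in catalog.disease_features if s.kind == "set_valued"]
    disease_text = [s.name for s in catalog.disease_features if s.kind == "text"]
    _fill_set_features(drug_table, drug_ids, drug_clusters, config.n_drug_clusters, drug_set, config, rng)
    _fill_text_features(drug_table, drug_ids, drug_clusters, config.n_drug_clusters, drug_text, config, rng)
    _fill_set_features(
        disease_table, disease_ids, disease_clusters, config.n_disease_clusters, disease_set, config, rng
    )
    _fill_text_features(
        disease_table, disease_ids, disease_clusters, config.n_disease_clusters, disease_text, config, rng
    )

    # associations: block-respecting with probability signal_strength
    diseases_by_cluster = [
        [s for s in disease_ids if disease_clusters[s] == h] for h in range(config.n_disease_clusters)
    ]
    n_pos = round(config.n_drugs * config.m_diseases * config.density)
    n_held = round(config.heldout_fraction * n_pos)
    drawn: list[tuple[tuple[str, str], bool]] = []
    seen: set[tuple[str, str]] = set()
    max_tries = 200 * (n_pos + n_held + 1)
    tries = 0
    while len(drawn) < n_pos + n_held and tries < max_tries:
        tries += 1
        d = drug_ids[rng.integers(0, config.n_drugs)]
        matched_draw = rng.random() < config.signal_strength
        if matched_draw:
            pool = diseases_by_cluster[drug_clusters[d] % config.n_disease_clusters]
            if not pool:
                continue
            s = pool[rng.integers(0, len(pool))]
        else:
            s = disease_ids[rng.integers(0, config.m_diseases)]
        if (d, s) in seen:
            continue
        seen.add((d, s))
        drawn.append(((d, s), matched_draw))
    if len(drawn) < n_pos + n_held:
        raise ValueError("infeasible density: could not draw enough distinct positive pairs")

    # withhold held-out truths, preferring block-respecting draws
    matched_idx = [i for i, (_, m) in enumerate(drawn) if m]
    other_idx = [i for i, (_, m) in enumerate(drawn) if not m]
    held_order = matched_idx + other_idx
    held_set = set(held_order[:n_held])
    heldout = sorted(drawn[i][0] for i in held_set)
    positives = [pair for i, (pair, _) in enumerate(drawn) if i not in held_set]

    return SyntheticDataset(
        config=config,
        catalog=catalog,
        drug_table=drug_table,
        disease_table=disease_table,
        index=AssociationIndex.from_pairs(positives),
        drug_clusters=drug_clusters,
        disease_clusters=disease_clusters,
        heldout_pairs=heldout,
    )


def write_fixture(dataset: SyntheticDataset, directory: str | Path, force: bool = False) -> dict[str, Path]:
    """Write the fixture directory: feature tables, associations, truths, config.

    Refuses to write into a non-empty directory unless ``force`` is set.
    Output is byte-deterministic for a fixed config.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        if not force:
            raise FileExistsError(f"{directory} is not empty; pass force=True to overwrite")
        shutil.rmtree(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "drug_features": directory / "drug_features.tsv",
        "disease_features": directory / "disease_features.tsv",
        "associations": directory / "associations.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "config.json",
    }
    dataset.drug_table.write(paths["drug_features"])
    dataset.disease_table.write(paths["disease_features"])
    dataset.index.write(paths["associations"])
    with open(paths["truth"], "w") as fh:
        fh.write("drug_id\tdisease_id\n")
        for d, s in sorted(dataset.heldout_pairs):
            fh.write(f"{d}\t{s}\n")
    meta = {
        "config": asdict(dataset.config),
        "drug_clusters": dataset.drug_clusters,
        "disease_clusters": dataset.disease_clusters,
    }
    with open(paths["config"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
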