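"""Hybrid semantic similarity space.

Concepts are represented by the semantic features people list for them
(property norms, e.g. "is comfortable" for *armchair*).  Each feature is
mapped into a distributional word-vector space by averaging the embedding
vectors of its content words; each concept is the average of its feature
vectors; the semantic representational dissimilarity matrix (RDM) is the
cosine distance between all concept pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Relational markers stripped from feature phrases before embedding lookup.
DEFAULT_STOPWORDS = frozenset(
    "is has have a an the of on in made used for to like by with".split()
)


class SemanticSpaceError(ValueError):
    """Raised when a feature or concept cannot be represented."""


@dataclass
class FeatureNorms:
    """Concept x feature weight table (binary presence in the minimal case)."""

    concepts: list[str]
    features: list[str]
    weights: np.ndarray  # (n_concepts, n_features), non-negative

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.concepts), len(self.features)):
            raise ValueError("weights shape does not match concept/feature lists")
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("concept names must be unique")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")
        if np.any((self.weights > 0).sum(axis=1) == 0):
            bad = [c for c, row in zip(self.concepts, self.weights) if not (row > 0).any()]
            raise ValueError(f"concepts with no features: {bad}")

    def features_of(self, concept: str) -> list[str]:
        i = self.concepts.index(concept)
        return [f for f, w in zip(self.features, self.weights[i]) if w > 0]

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureNorms":
        """Read norms from long TSV (concept, feature, weight) or a wide CSV matrix."""
        path = Path(path)
        head = path.read_text().splitlines()[0] if path.stat().st_size else ""
        if "\t" in head:
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["concept", "feature", "weight"])
            if str(df.iloc[0, 0]).lower() == "concept":  # tolerate a header line
                df = df.iloc[1:]
            df["weight"] = df["weight"].astype(float)
            wide = df.pivot_table(index="concept", columns="feature",
                                  values="weight", fill_value=0.0, sort=False)
        else:
            wide = pd.read_csv(path, index_col=0)
        return cls(list(wide.index), list(wide.columns), wide.to_numpy(dtype=float))

    def to_long_tsv(self, path: str | Path) -> None:
        rows = []
        for i, c in enumerate(self.concepts):
            for j, f in enumerate(self.features):
                if self.weights[i, j] > 0:
                    rows.append((c, f, self.weights[i, j]))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class EmbeddingTable:
    """word -> fixed-dimension vector lookup."""

    vectors: dict[str, np.ndarray]
    dimension: int

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("empty vocabulary")
        for w, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dimension,):
                raise ValueError(f"vector for {w!r} has length {v.shape}, expected {self.dimension}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite vector for {w!r}")
            self.vectors[w] = v

    @property
    def vocabulary(self) -> set[str]:
        return set(self.vectors)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    @classmethod
    def from_file(cls, path: str | Path) -> "EmbeddingTable":
        """Read the standard text embedding format (word then floats per line).

        An optional leading "V d" header line is tolerated.
        """
        vectors: dict[str, np.ndarray] = {}
        dim = None
        with open(path) as fh:
            for lineno, line in enumerate(fh):
                parts = line.rstrip("\n").split()
                if not parts:
                    continue
                if lineno == 0 and len(parts) == 2:
                    try:
                        int(parts[0]), int(parts[1])
                        continue  # header line
                    except ValueError:
                        pass
                word, vals = parts[0], np.array(parts[1:], dtype=float)
                if dim is None:
                    dim = len(vals)
                elif len(vals) != dim:
                    raise ValueError(f"inconsistent dimension at line {lineno + 1}")
                vectors[word] = vals
        if dim is None:
            raise ValueError(f"no vectors in {path}")
        return cls(vectors, dim)

    def to_file(self, path: str | Path, header: bool = False) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for w, v in self.vectors.items():
                fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")


@dataclass
class ConceptVectorSet:
    """Concept vectors with per-concept provenance of features/words used."""

    concepts: list[str]
    matrix: np.ndarray  # (n_concepts, d)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.concepts):
            raise ValueError("row count != concept count")


@dataclass
class RDM:
    """Symmetric item x item dissimilarity matrix, zero diagonal."""

    items: list[str]
    values: np.ndarray
    metric: str  # "cosine" | "circular"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RDM not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal not zero")
        hi = 2.0 if self.metric == "cosine" else np.pi
        if self.values.min() < -1e-10 or self.values.max() > hi + 1e-10:
            raise ValueError(f"{self.metric} RDM entries outside [0, {hi}]")

    def vectorize(self) -> np.ndarray:
        """Strictly-lower-triangle vector, row-major."""
        i, j = np.tril_indices(len(self.items), k=-1)
        return self.values[i, j]

    def reorder(self, items: list[str]) -> "RDM":
        idx = [self.items.index(it) for it in items]
        return RDM(list(items), self.values[np.ix_(idx, idx)], self.metric)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.items, columns=self.items).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, metric: str = "cosine") -> "RDM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.index], df.to_numpy(dtype=float), metric)


def extract_content_words(feature: str, stopwords=DEFAULT_STOPWORDS) -> list[str]:
    """Lowercased tokens of a feature phrase with relational markers removed.

    "is comfortable" -> ["comfortable"]; order is preserved.
    """
    if not feature or not feature.strip():
        raise SemanticSpaceError("empty feature string")
    words = [w for w in feature.lower().split() if w not in stopwords]
    if not words:
        raise SemanticSpaceError(f"feature-has-no-content-words: {feature!r}")
    return words


def feature_vector(feature: str, emb: EmbeddingTable,
                   stopwords=DEFAULT_STOPWORDS) -> np.ndarray:
    """Mean of embedding vectors of the feature's in-vocabulary content words."""
    words = extract_content_words(feature, stopwords)
    known = [w for w in words if w in emb]
    missing = [w for w in words if w not in emb]
    if missing:
        logger.warning("feature %r: out-of-vocabulary words %s", feature, missing)
    if not known:
        raise SemanticSpaceError(f"feature-oov: {feature!r}")
    return np.mean([emb[w] for w in known], axis=0)


def concept_vector(concept: str, norms: FeatureNorms, emb: EmbeddingTable,
                   stopwords=DEFAULT_STOPWORDS, weighted: bool = False,
                   provenance: dict | None = None) -> np.ndarray:
    """Mean of the concept's feature vectors (weight-proportional if ``weighted``).

    Features that are fully out of vocabulary are skipped with a warning and
    recorded in ``provenance``; a concept losing all features is an error.
    """
    if concept not in norms.concepts:
        raise SemanticSpaceError(f"unknown concept {concept!r}")
    i = norms.concepts.index(concept)
    vecs, wts, used, skipped = [], [], [], []
    for f, w in zip(norms.features, norms.weights[i]):
        if w <= 0:
            continue
        try:
            vecs.append(feature_vector(f, emb, stopwords))
            wts.append(w if weighted else 1.0)
            used.append(f)
        except SemanticSpaceError:
            skipped.append(f)
    if provenance is not None:
        provenance.update({"features_used": used, "features_skipped": skipped})
    if not vecs:
        raise SemanticSpaceError(f"concept-unrepresentable: {concept!r}")
    if skipped:
        logger.warning("concept %r: skipped features %s", concept, skipped)
    wts_arr = np.asarray(wts)
    return np.asarray(vecs).T @ (wts_arr / wts_arr.sum())


def concept_vectors(norms: FeatureNorms, emb: EmbeddingTable,
                    stopwords=DEFAULT_STOPWORDS, weighted: bool = False) -> ConceptVectorSet:
    """Concept vectors for every concept in the norms, with provenance."""
    rows, prov = [], []
    for c in norms.concepts:
        p: dict = {"concept": c}
        rows.append(concept_vector(c, norms, emb, stopwords, weighted, p))
        prov.append(p)
    return ConceptVectorSet(list(norms.concepts), np.asarray(rows), prov)


def cosine_rdm(items: list[str], matrix: np.ndarray) -> RDM:
    """Cosine-distance RDM of row vectors: d_ij = 1 - vi.vj / (|vi||vj|)."""
    matrix = np.asarray(matrix, dtype=float)
    norms_ = np.linalg.norm(matrix, axis=1)
    if np.any(norms_ == 0):
        bad = [items[k] for k in np.flatnonzero(norms_ == 0)]
        raise SemanticSpaceError(f"zero-vector: {bad}")
    unit = matrix / norms_[:, None]
    d = 1.0 - unit @ unit.T
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return RDM(list(items), d, "cosine")


def semantic_rdm(cvs: ConceptVectorSet) -> RDM:
    """Cosine-distance RDM between all concept-vector pairs."""
    if len(cvs.concepts) < 2:
        raise SemanticSpaceError("need at least 2 concepts")
    return cosine_rdm(cvs.concepts, cvs.matrix)
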