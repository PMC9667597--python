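"""Jaccard similarity profiles from binary drug descriptors.

A drug is described by one sparse binary vector per feature type (chemical
substructures, targets, enzymes, pathways, ...). Because those raw vectors
are high-dimensional and mostly zero, the model instead consumes a
*similarity profile*: for each feature type, the drug's Jaccard similarity
J(A, B) = |A∩B| / |A|+|B|−|A∩B| against every drug in the dataset. With T
feature types and n drugs the profile is a length T·n vector; blocks are
concatenated in a declared, persisted feature-type order because the model
is order-sensitive.

Profiles are computed against *all* drugs in the descriptor table —
including drugs that only ever appear in test folds — so the profile width
is a property of the dataset, not of a split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DescriptorSet",
    "SimilarityProfile",
    "jaccard_similarity",
    "build_similarity_profiles",
    "DEFAULT_FEATURE_ORDER",
]

DEFAULT_FEATURE_ORDER = ("substructure", "target", "enzyme", "pathway")


class EmptyDescriptorWarning(UserWarning):
    """Both descriptor sets empty: Jaccard 0/0 defined as 0."""


@dataclass
class DescriptorSet:
    """Per-drug binary descriptor vectors, one matrix block per feature type.

    ``blocks[t]`` has shape (n_drugs, n_descriptors_t) with entries in {0,1};
    all blocks share the ordering of ``drug_ids``.
    """

    drug_ids: list[str]
    blocks: dict[str, np.ndarray]

    def __post_init__(self):
        self.drug_ids = [str(d) for d in self.drug_ids]
        if len(self.drug_ids) < 2:
            raise ValueError("a DescriptorSet needs at least 2 drugs")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if not self.blocks:
            raise ValueError("a DescriptorSet needs at least one feature type")
        clean = {}
        for name, mat in self.blocks.items():
            mat = np.asarray(mat)
            if mat.ndim != 2 or mat.shape[0] != len(self.drug_ids):
                raise ValueError(
                    f"block {name!r}: expected ({len(self.drug_ids)}, k) matrix, "
                    f"got shape {mat.shape}"
                )
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"block {name!r} contains non-binary values")
            clean[name] = mat.astype(np.uint8)
        self.blocks = clean

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def feature_types(self) -> list[str]:
        return list(self.blocks)


@dataclass
class SimilarityProfile:
    """Concatenated per-type Jaccard similarity blocks; one row per drug.

    ``matrix`` has shape (n_drugs, T·n_drugs); ``feature_types`` records the
    block order; column block t spans [t·n_drugs, (t+1)·n_drugs).
    """

    drug_ids: list[str]
    matrix: np.ndarray
    feature_types: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.drug_ids)
        if self.matrix.shape != (n, len(self.feature_types) * n):
            raise ValueError(
                f"profile matrix shape {self.matrix.shape} inconsistent with "
                f"{n} drugs x {len(self.feature_types)} feature types"
            )
        if self.matrix.min() < 0.0 or self.matrix.max() > 1.0:
            raise ValueError("profile values must lie in [0, 1]")
        self._index = {d: i for i, d in enumerate(self.drug_ids)}

    @property
    def fea_dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def vector(self, drug_id: str) -> np.ndarray:
        try:
            return self.matrix[self._index[drug_id]]
        except KeyError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def vectors(self, drug_ids) -> np.ndarray:
        missing = [d for d in drug_ids if d not in self._index]
        if missing:
            raise KeyError(f"unknown drug ids: {missing}")
        return self.matrix[[self._index[d] for d in drug_ids]]

    def block(self, feature_type: str) -> np.ndarray:
        """The (n_drugs, n_drugs) similarity block of one feature type."""
        t = self.feature_types.index(feature_type)
        n = self.n_drugs
        return self.matrix[:, t * n:(t + 1) * n]


def jaccard_similarity(a, b) -> float:
    """Jaccard similarity of two equal-length binary vectors read as
    indicator sets. Both-empty is defined as 0.0 with a warning: an empty
    descriptor set carries no similarity evidence."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = float(np.count_nonzero((a != 0) & (b != 0)))
    union = float(np.count_nonzero((a != 0) | (b != 0)))
    if union == 0.0:
        warnings.warn(
            "Jaccard of two empty descriptor sets defined as 0.0",
            EmptyDescriptorWarning,
            stacklevel=2,
        )
        return 0.0
    return inter / union


def _jaccard_block(mat: np.ndarray) -> np.ndarray:
    """All-pairs Jaccard for the rows of a binary matrix; 0/0 -> 0."""
    m = mat.astype(np.float64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return sim


def build_similarity_profiles(
    d: DescriptorSet,
    feature_order: list[str] | None = None,
    include_self: bool = True,
) -> SimilarityProfile:
    """All-against-all Jaccard profiles, one block per feature type.

    ``feature_order`` fixes the concatenation order (default: the order the
    blocks were declared in). ``include_self=False`` masks each drug's
    self-similarity column entry to 0 while keeping the profile width fixed.
    """
    order = list(feature_order) if feature_order is not None else d.feature_types
    missing = [t for t in order if t not in d.blocks]
    if missing:
        raise ValueError(f"feature types not in descriptor set: {missing}")
    blocks = []
    for t in order:
        mat = d.blocks[t]
        if (mat.sum(axis=1) == 0).any():
            n_empty = int((mat.sum(axis=1) == 0).sum())
            warnings.warn(
                f"{n_empty} drug(s) have an empty {t!r} descriptor set; "
                "their similarities in that block are 0",
                EmptyDescriptorWarning,
                stacklevel=2,
            )
        sim = _jaccard_block(mat)
        if not include_self:
            np.fill_diagonal(sim, 0.0)
        blocks.append(sim)
    return SimilarityProfile(
        drug_ids=list(d.drug_ids),
        matrix=np.concatenate(blocks, axis=1),
        feature_types=order,
    )
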