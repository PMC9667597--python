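"""Synthetic drug descriptor tables and DDI label tables with planted,
recoverable class structure.

The generator emulates the statistical shape the model consumes — N drugs,
T feature types of sparse binary descriptors, C imbalanced interaction
classes over unordered drug pairs — while planting a signal the
similarity-profile pathway can recover:

* drugs belong to latent *archetypes*; each archetype has a template bit
  pattern per feature type, and a drug's bits are its template with a small
  fraction of bits flipped (``bit_noise``);
* every interaction class is keyed to a set of (archetype, archetype)
  combinations, so the pair's class is a deterministic function of the two
  drugs' archetypes — learnable from descriptors, not memorisable;
* class sizes follow a power law ``share(c) ∝ (c+1)^(-imbalance_exponent)``
  (class 0 largest), produced by allocating archetype pairs to classes
  proportionally to the target shares and then subsampling candidate drug
  pairs to the target counts;
* a fraction ``label_noise`` of pair labels is flipped uniformly to another
  class.

Everything is reproducible from ``SynthConfig.seed`` alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .features import DescriptorSet
from .splits_eval import DDIDataset

__all__ = [
    "SynthConfig",
    "generate",
    "paper_shaped_preset",
    "rare_class_preset",
    "nearest_archetype_labels",
    "DATASET1_SHAPE",
    "DATASET2_SHAPE",
]

FEATURE_TYPE_NAMES = ("substructure", "target", "enzyme", "pathway")

# benchmark dataset geometries the presets scale from:
# (n_drugs, n_pairs, n_classes, n_feature_types)
DATASET1_SHAPE = (572, 74_528, 65, 4)
DATASET2_SHAPE = (1_258, 323_539, 100, 3)


@dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 60
    n_feature_types: int = 4
    descriptors_per_type: int = 256
    bit_density: float = 0.1
    n_classes: int = 6
    n_archetypes: int = 8
    pair_coverage: float = 0.5
    imbalance_exponent: float = 1.5
    label_noise: float = 0.0
    bit_noise: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_archetypes > self.n_drugs:
            raise ValueError("n_archetypes must not exceed n_drugs")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        n_arch_pairs = self.n_archetypes * (self.n_archetypes + 1) // 2
        if self.n_classes > n_arch_pairs:
            raise ValueError(
                f"{self.n_classes} classes cannot be keyed to "
                f"{n_arch_pairs} archetype pairs"
            )
        if not 0.0 < self.bit_density < 1.0:
            raise ValueError("bit_density must be in (0, 1)")
        if not 0.0 < self.pair_coverage <= 1.0:
            raise ValueError("pair_coverage must be in (0, 1]")
        if self.imbalance_exponent < 0:
            raise ValueError("imbalance_exponent must be >= 0")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        if not 0.0 <= self.bit_noise < 0.5:
            raise ValueError("bit_noise must be in [0, 0.5)")

    def to_dict(self) -> dict:
        return asdict(self)


def _class_shares(n_classes: int, exponent: float) -> np.ndarray:
    w = (np.arange(1, n_classes + 1, dtype=np.float64)) ** (-exponent)
    return w / w.sum()


def _largest_remainder(weights: np.ndarray, total: int, floor: int = 0) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` with a
    per-cell floor; deterministic."""
    raw = weights * total
    counts = np.maximum(np.floor(raw).astype(np.intp), floor)
    diff = total - counts.sum()
    if diff > 0:
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        for i in order[:diff]:
            counts[i] += 1
    elif diff < 0:
        order = np.argsort(-counts, kind="stable")  # shave the largest cells
        i = 0
        while diff < 0:
            c = order[i % len(order)]
            if counts[c] > floor:
                counts[c] -= 1
                diff += 1
            i += 1
    return counts


def generate(cfg: SynthConfig):
    """Draw a (DescriptorSet, DDIDataset, ground_truth) triple from ``cfg``.

    ``ground_truth`` maps: ``archetype_of`` drug id -> archetype,
    ``class_of_archpair`` "a,b" (a<=b) -> class, ``templates`` feature type
    -> (n_archetypes, D) binary array, ``clean_labels`` record index ->
    pre-noise label.
    """
    rng = np.random.default_rng(cfg.seed)
    n, a_n = cfg.n_drugs, cfg.n_archetypes
    width = len(str(n - 1))
    drug_ids = [f"D{i:0{width}d}" for i in range(n)]

    # --- archetype templates and drug bits -------------------------------
    type_names = [
        FEATURE_TYPE_NAMES[t] if t < len(FEATURE_TYPE_NAMES) else f"feature{t}"
        for t in range(cfg.n_feature_types)
    ]
    arch_of = np.concatenate(
        [np.arange(a_n), rng.integers(0, a_n, size=n - a_n)]
    )
    rng.shuffle(arch_of)
    templates: dict[str, np.ndarray] = {}
    blocks: dict[str, np.ndarray] = {}
    for t in type_names:
        tmpl = (rng.random((a_n, cfg.descriptors_per_type)) < cfg.bit_density)
        empty = ~tmpl.any(axis=1)
        if empty.any():  # every archetype keeps at least one bit per type
            tmpl[empty, rng.integers(0, cfg.descriptors_per_type, empty.sum())] = True
        templates[t] = tmpl.astype(np.uint8)
        flips = rng.random((n, cfg.descriptors_per_type)) < cfg.bit_noise
        blocks[t] = (templates[t][arch_of].astype(bool) ^ flips).astype(np.uint8)
    descriptors = DescriptorSet(drug_ids=drug_ids, blocks=blocks)

    # --- key classes to archetype pairs ----------------------------------
    arch_pairs = [(i, j) for i in range(a_n) for j in range(i, a_n)]
    rng.shuffle(arch_pairs)
    shares = _class_shares(cfg.n_classes, cfg.imbalance_exponent)
    per_class_ap = _largest_remainder(shares, len(arch_pairs), floor=1)
    class_of_ap: dict[tuple[int, int], int] = {}
    pos = 0
    for c, k in enumerate(per_class_ap):
        for ap in arch_pairs[pos:pos + k]:
            class_of_ap[ap] = c
        pos += k

    # --- candidate drug pairs grouped by planted class --------------------
    iu, ju = np.triu_indices(n, k=1)
    ai, aj = arch_of[iu], arch_of[ju]
    lo, hi = np.minimum(ai, aj), np.maximum(ai, aj)
    pair_class = np.array([class_of_ap[(x, y)] for x, y in zip(lo, hi)])

    total_target = max(cfg.n_classes, int(round(cfg.pair_coverage * len(iu))))
    targets = _largest_remainder(shares, total_target, floor=1)
    avail = np.bincount(pair_class, minlength=cfg.n_classes)
    take = np.minimum(targets, avail)
    shortfall = int(total_target - take.sum())
    if shortfall > 0:  # redistribute to classes with spare candidates
        spare_order = np.argsort(-(avail - take), kind="stable")
        for c in spare_order:
            room = int(avail[c] - take[c])
            add = min(room, shortfall)
            take[c] += add
            shortfall -= add
            if shortfall == 0:
                break

    chosen: list[int] = []
    for c in range(cfg.n_classes):
        idx = np.flatnonzero(pair_class == c)
        if take[c] > 0 and len(idx) > 0:
            chosen.extend(rng.choice(idx, size=int(take[c]), replace=False).tolist())
    chosen = np.array(sorted(chosen), dtype=np.intp)

    clean = pair_class[chosen].copy()
    labels = clean.copy()
    if cfg.label_noise > 0:
        flip = rng.random(len(labels)) < cfg.label_noise
        offsets = rng.integers(1, cfg.n_classes, size=len(labels))
        labels[flip] = (labels[flip] + offsets[flip]) % cfg.n_classes

    records = [
        (drug_ids[iu[p]], drug_ids[ju[p]], int(y))
        for p, y in zip(chosen, labels)
    ]
    dataset = DDIDataset(
        records=records, n_classes=cfg.n_classes, drug_universe=set(drug_ids)
    )
    ground_truth = {
        "archetype_of": {d: int(a) for d, a in zip(drug_ids, arch_of)},
        "class_of_archpair": {f"{x},{y}": c for (x, y), c in class_of_ap.items()},
        "templates": templates,
        "clean_labels": clean.tolist(),
    }
    return descriptors, dataset, ground_truth


def nearest_archetype_labels(descriptors: DescriptorSet, ground_truth: dict,
                             dataset: DDIDataset) -> np.ndarray:
    """Labels implied by nearest-template archetype assignment: the oracle
    classifier for the planted structure (exact when bit_noise == 0)."""
    templates = ground_truth["templates"]
    stacked = np.concatenate(
        [descriptors.blocks[t].astype(np.int16) for t in templates], axis=1
    )
    tmpl = np.concatenate(
        [templates[t].astype(np.int16) for t in templates], axis=1
    )
    # Hamming distance drug x archetype
    dists = np.abs(stacked[:, None, :] - tmpl[None, :, :]).sum(axis=2)
    arch = dists.argmin(axis=1)
    index = {d: i for i, d in enumerate(descriptors.drug_ids)}
    cls_map = {
        tuple(map(int, k.split(","))): v
        for k, v in ground_truth["class_of_archpair"].items()
    }
    out = []
    for a, b, _ in dataset.records:
        x, y = sorted((arch[index[a]], arch[index[b]]))
        out.append(cls_map[(int(x), int(y))])
    return np.array(out, dtype=np.intp)


def _scaled(value: int, scale: float, minimum: int) -> int:
    return max(minimum, int(math.floor(value * scale + 0.5)))


def paper_shaped_preset(which: str = "dataset1", scale: float = 1.0,
                        seed: int = 0, label_noise: float = 0.05) -> SynthConfig:
    """A config whose drug/class/pair counts mirror one of the two benchmark
    dataset geometries, scaled by ``scale`` in drug and class counts (pair
    counts then scale quadratically through the preserved pair coverage)."""
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    try:
        n_drugs, n_pairs, n_classes, n_types = {
            "dataset1": DATASET1_SHAPE, "dataset2": DATASET2_SHAPE,
        }[which]
    except KeyError:
        raise ValueError(f"unknown preset {which!r}") from None
    coverage = n_pairs / (n_drugs * (n_drugs - 1) / 2)
    c = _scaled(n_classes, scale, 2)
    if c < 2:
        raise ValueError("scale produces fewer than 2 classes")
    # enough archetype pairs for ~3x the class count, for allocation headroom
    a = 2
    while a * (a + 1) // 2 < 3 * c:
        a += 1
    n = _scaled(n_drugs, scale, max(10, a))
    return SynthConfig(
        n_drugs=n,
        n_feature_types=n_types,
        descriptors_per_type=256,
        bit_density=0.1,
        n_classes=c,
        n_archetypes=min(a, n),
        pair_coverage=min(1.0, coverage),
        imbalance_exponent=1.5,
        label_noise=label_noise,
        bit_noise=0.02,
        seed=seed,
    )


def rare_class_preset(seed: int = 0) -> SynthConfig:
    """Imbalanced fixture for rare-class experiments: 20 power-law classes
    over 100 drugs, guaranteeing several classes below 1% support."""
    return SynthConfig(
        n_drugs=100,
        n_feature_types=4,
        descriptors_per_type=256,
        bit_density=0.1,
        n_classes=20,
        n_archetypes=16,
        pair_coverage=0.5,
        imbalance_exponent=1.5,
        label_noise=0.02,
        bit_noise=0.02,
        seed=seed,
    )
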