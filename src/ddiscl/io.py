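"""CSV/JSON/YAML readers and writers for descriptors, DDI tables, profiles
and run configuration.

Canonical interchange is RFC-4180 CSV with a header row, UTF-8. Descriptors
arrive either as one wide CSV per feature type (drug_id index column,
binary descriptor columns) or as a single long-format CSV with columns
``drug_id, feature_type, descriptor_id``. DDI tables have columns
``drugA, drugB, label``; labels may be arbitrary strings and are re-indexed
to contiguous integers in sorted order, with the mapping persisted as JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import DescriptorSet, SimilarityProfile
from .splits_eval import DDIDataset

__all__ = [
    "FormatError",
    "read_descriptor_csvs",
    "read_descriptors_long",
    "write_descriptor_csvs",
    "read_ddis",
    "write_ddis",
    "write_profile",
    "read_profile",
    "write_label_mapping",
    "read_label_mapping",
    "load_run_config",
]

logger = logging.getLogger("ddiscl")


class FormatError(ValueError):
    """An input file violates the expected format."""


def _binary_frame(df: pd.DataFrame, path) -> np.ndarray:
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-binary value {values[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    return values.astype(np.uint8)


def read_descriptor_csvs(paths: dict[str, str | Path]) -> DescriptorSet:
    """One wide CSV per feature type: first column drug_id, remaining
    columns binary descriptors. Drugs are aligned on the union of ids;
    drugs missing from a file get an all-zero block with a warning."""
    if not paths:
        raise FormatError("no descriptor files given")
    frames = {}
    for ftype, path in paths.items():
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise FormatError(f"{path}: duplicate drug ids")
        frames[ftype] = df
    all_ids = sorted(set().union(*(set(df.index) for df in frames.values())))
    shared = set.intersection(*(set(df.index) for df in frames.values()))
    if not shared:
        raise FormatError("no drug id occurs in every descriptor file")
    blocks = {}
    for ftype, df in frames.items():
        missing = [d for d in all_ids if d not in df.index]
        if missing:
            warnings.warn(
                f"{len(missing)} drug(s) missing a {ftype!r} block; filled "
                "with zeros", UserWarning, stacklevel=2,
            )
        aligned = df.reindex(all_ids, fill_value=0)
        blocks[ftype] = _binary_frame(aligned, paths[ftype])
    return DescriptorSet(drug_ids=all_ids, blocks=blocks)


def read_descriptors_long(path: str | Path) -> DescriptorSet:
    """Long format: columns drug_id, feature_type, descriptor_id; presence
    of a row means the bit is set."""
    df = pd.read_csv(path, dtype=str)
    required = {"drug_id", "feature_type", "descriptor_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    drug_ids = sorted(df["drug_id"].unique())
    idx = {d: i for i, d in enumerate(drug_ids)}
    blocks = {}
    for ftype, grp in df.groupby("feature_type", sort=True):
        descs = sorted(grp["descriptor_id"].unique())
        didx = {d: j for j, d in enumerate(descs)}
        mat = np.zeros((len(drug_ids), len(descs)), dtype=np.uint8)
        mat[[idx[d] for d in grp["drug_id"]],
            [didx[d] for d in grp["descriptor_id"]]] = 1
        blocks[str(ftype)] = mat
    return DescriptorSet(drug_ids=drug_ids, blocks=blocks)


def write_descriptor_csvs(d: DescriptorSet, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for ftype, mat in d.blocks.items():
        df = pd.DataFrame(
            mat,
            index=pd.Index(d.drug_ids, name="drug_id"),
            columns=[f"{ftype}_{j}" for j in range(mat.shape[1])],
        )
        path = out_dir / f"descriptors_{ftype}.csv"
        df.to_csv(path)
        written[ftype] = path
    return written


def read_ddis(path: str | Path, label_mapping: dict[str, int] | None = None,
              n_classes: int | None = None,
              drug_universe: set[str] | None = None
              ) -> tuple[DDIDataset, dict[str, int]]:
    """Read (drugA, drugB, label) triplets. Returns the dataset and the
    label -> integer mapping (built in sorted label order unless given)."""
    df = pd.read_csv(path, dtype=str)
    required = {"drugA", "drugB", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    seen: dict[frozenset, tuple[int, str]] = {}
    for i, (a, b, y) in enumerate(zip(df["drugA"], df["drugB"], df["label"])):
        if a == b:
            raise FormatError(f"{path}: row {i}: self-pair ({a}, {a})")
        key = frozenset((a, b))
        if key in seen:
            j, prev = seen[key]
            msg = f"{path}: rows {j} and {i}: duplicate pair ({a}, {b})"
            if prev != y:
                msg += f" with conflicting labels {prev!r} vs {y!r}"
            raise FormatError(msg)
        seen[key] = (i, y)
    if label_mapping is None:
        label_mapping = {lab: i for i, lab in enumerate(sorted(df["label"].unique()))}
    unknown = set(df["label"]) - set(label_mapping)
    if unknown:
        raise FormatError(f"{path}: labels not in mapping: {sorted(unknown)}")
    c = n_classes if n_classes is not None else max(label_mapping.values()) + 1
    records = [
        (a, b, label_mapping[y])
        for a, b, y in zip(df["drugA"], df["drugB"], df["label"])
    ]
    universe = drug_universe or (set(df["drugA"]) | set(df["drugB"]))
    return DDIDataset(records=records, n_classes=c, drug_universe=universe), label_mapping


def write_ddis(ds: DDIDataset, path: str | Path,
               label_names: dict[int, str] | None = None) -> None:
    rows = [
        {"drugA": a, "drugB": b,
         "label": label_names[y] if label_names else y}
        for a, b, y in ds.records
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["drugA", "drugB", "label"]).to_csv(path, index=False)


def write_label_mapping(mapping: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(mapping, indent=1, sort_keys=True))


def read_label_mapping(path: str | Path) -> dict[str, int]:
    return {k: int(v) for k, v in json.loads(Path(path).read_text()).items()}


def write_profile(profile: SimilarityProfile, csv_path: str | Path) -> None:
    """Profile matrix as CSV (drug_id index) plus a JSON sidecar recording
    feature-type block boundaries."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    n = profile.n_drugs
    cols = [
        f"{t}:{d}" for t in profile.feature_types for d in profile.drug_ids
    ]
    pd.DataFrame(
        profile.matrix, index=pd.Index(profile.drug_ids, name="drug_id"),
        columns=cols,
    ).to_csv(csv_path)
    sidecar = {
        "feature_types": profile.feature_types,
        "block_boundaries": {
            t: [i * n, (i + 1) * n] for i, t in enumerate(profile.feature_types)
        },
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_profile(csv_path: str | Path) -> SimilarityProfile:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return SimilarityProfile(
        drug_ids=[str(d) for d in df.index],
        matrix=df.to_numpy(dtype=np.float64),
        feature_types=list(sidecar["feature_types"]),
    )


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run config into a plain dict of sections (paths,
    training, network, synth, task/fold selections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: run config must be a mapping")
    return cfg
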