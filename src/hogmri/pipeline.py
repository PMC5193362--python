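"""End-to-end pipeline: volumes -> HOG features -> selection -> hold-out report.

Stages run in a fixed order: read each subject's NIfTI, z-normalise,
time-average if 4D, extract the 3D HOG descriptor, optionally
concatenate cleaned personal-characteristic features, split off a
label-balanced hold-out set (or honour an explicit split file), run the
MHPC learner/feature selection on the training part, and score the
winner on the hold-out part.  Every run writes a JSON manifest with the
config hash and seeds so it can be replayed bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .hog import HOGParams, extract_hog
from .learners import EvalReport, make_learner_bank
from .mhpc import LabeledDataset, MHPCConfig, SelectionResult, evaluate_holdout, mhpc_select
from .personal import clean_personal_table, concat_features
from .volume_io import Scan4D, read_volume, time_average, znormalize

log = logging.getLogger("hogmri")


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run.

    ``labels_tsv`` lists subjects as (subject_id, path, label); volume
    paths are resolved relative to the TSV.  ``split_file`` (optional
    TSV: subject_id, role in {train, test}) overrides the random
    ``holdout_fraction`` split.  All randomness flows from ``seed``.
    """

    labels_tsv: str
    out_dir: str = "hogmri_out"
    personal_csv: str | None = None
    split_file: str | None = None
    holdout_fraction: float = 0.2
    seed: int = 0
    cell_size_voxels: int = 8
    block_cells: int = 2
    block_stride_cells: int = 1
    epsilon: float = 1e-5
    patience: int = 20
    k_max: int = 1000
    strict_per_fold: bool = False
    mrmr_variant: str = "MID"
    learners: list[str] | None = None  # None = full 13-member bank

    def hog_params(self) -> HOGParams:
        return HOGParams(self.cell_size_voxels, self.block_cells,
                         self.block_stride_cells, self.epsilon)

    def mhpc_config(self) -> MHPCConfig:
        return MHPCConfig(patience=self.patience, k_max=self.k_max,
                          seed=self.seed, strict_per_fold=self.strict_per_fold,
                          mrmr_variant=self.mrmr_variant)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def split_train_test(dataset: LabeledDataset, fraction: float,
                     seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Label-balanced random split: ``fraction`` of each class to training.

    Disjoint, union = input; per-class training counts are
    ``round(fraction * n_class)``, so class proportions are preserved
    to within one subject.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(dataset.y):
        idx = np.flatnonzero(dataset.y == cls)
        n_train = int(round(fraction * idx.size))
        if n_train < 1 or n_train >= idx.size:
            raise ValueError(f"class {cls!r} too small to split at fraction {fraction}")
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def extract_features(labels_tsv, params: HOGParams) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read, z-normalise, time-average and HOG-encode every listed subject."""
    labels_tsv = Path(labels_tsv)
    table = pd.read_csv(labels_tsv, sep="\t")
    for col in ("subject_id", "path", "label"):
        if col not in table.columns:
            raise SchemaError(f"label table {labels_tsv} lacks column {col!r}")
    rows, labels, ids = [], [], []
    for rec in table.itertuples(index=False):
        path = labels_tsv.parent / rec.path
        try:
            vol = znormalize(read_volume(path))
            if isinstance(vol, Scan4D):
                vol = time_average(vol)
            desc = extract_hog(vol, params)
        except Exception as exc:
            raise type(exc)(f"[extract, subject {rec.subject_id}] {exc}") from exc
        rows.append(desc.features)
        labels.append(int(rec.label))
        ids.append(str(rec.subject_id))
    return np.vstack(rows), np.asarray(labels), ids


def _apply_split_file(dataset: LabeledDataset, split_file) -> tuple[LabeledDataset, LabeledDataset]:
    roles = pd.read_csv(split_file, sep="\t").set_index("subject_id")["role"]
    roles.index = roles.index.astype(str)
    missing = [s for s in dataset.subject_ids if s not in roles.index]
    if missing:
        raise SchemaError(f"split file lacks subjects {missing[:5]}")
    is_train = np.array([roles[s] == "train" for s in dataset.subject_ids])
    return dataset.subset(np.flatnonzero(is_train)), dataset.subset(np.flatnonzero(~is_train))


def run_pipeline(config: RunConfig) -> tuple[SelectionResult, EvalReport, dict]:
    """Execute the full pipeline and write all artifacts to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.digest(),
                      "seed": config.seed, "stages": []}

    def stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        dt = time.perf_counter() - t0
        log.info("stage %-12s %6.2f s", name, dt)
        manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
        return result

    X, y, ids = stage("extract", lambda: extract_features(config.labels_tsv,
                                                          config.hog_params()))
    log.info("extracted %d subjects x %d HOG features", *X.shape)

    if config.personal_csv:
        def fuse():
            table = pd.read_csv(config.personal_csv)
            keep = table[table["subject_id"].astype(str).isin(ids)]
            cleaned = clean_personal_table(keep.set_index(keep["subject_id"].astype(str))
                                           .drop(columns=["subject_id"]))
            cleaned.insert(0, "subject_id", cleaned.index)
            return concat_features(X, cleaned, y, ids)
        dataset, provenance = stage("fuse_personal", fuse)
    else:
        dataset = LabeledDataset(X, y, subject_ids=ids)
        provenance = {n: "image" for n in dataset.feature_names}

    if config.split_file:
        d_train, d_test = stage("split", lambda: _apply_split_file(dataset, config.split_file))
    else:
        d_train, d_test = stage("split", lambda: split_train_test(
            dataset, 1.0 - config.holdout_fraction, config.seed))
    manifest["n_train"], manifest["n_test"] = d_train.n, d_test.n

    bank = make_learner_bank()
    if config.learners:
        bank = [s for s in bank if s.name in config.learners]
    result = stage("select", lambda: mhpc_select(d_train, bank, config.mhpc_config()))
    report = stage("evaluate", lambda: evaluate_holdout(result, d_test))

    manifest["selection"] = result.to_manifest()
    manifest["holdout"] = report.to_dict()
    manifest["n_features"] = {"total": dataset.d,
                              "image": sum(v == "image" for v in provenance.values()),
                              "personal": sum(v == "personal" for v in provenance.values())}
    (out / "selection.json").write_text(json.dumps(result.to_manifest(), indent=2))
    (out / "audit_log.tsv").write_text(result.audit_tsv())
    (out / "holdout_report.json").write_text(report.to_json())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config.to_yaml(out / "config.yaml")
    return result, report, manifest
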