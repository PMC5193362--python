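"""Synthetic cohorts with class-dependent oriented texture.

Every stage of the pipeline is testable without downloading imaging
data: this module generates two-class cohorts of volumes in which the
patient class carries a sinusoidal grating — an oriented-gradient
signature that the HOG descriptor is, by construction, sensitive to —
confined to a fixed central sub-block and added on top of white
Gaussian noise; plus matching phenotypic tables with missing entries.

The grating runs along the (1, 1, 0) direction with an 8-voxel
wavelength and a per-subject random phase, so no single voxel is
informative but the oriented-gradient texture of the sub-block is.
``effect`` scales its amplitude relative to ``noise_sd``; ``effect=0``
yields a null cohort in which both classes are identically
distributed.  One global seed fans out to per-subject streams
``(seed, subject index)``, so a cohort can be extended without
regenerating existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import Volume3D, write_volume

#: Wavelength (voxels) and direction of the planted grating.
GRATING_WAVELENGTH = 8.0


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic two-class cohort."""

    n_per_class: int = 100
    dims: tuple[int, int, int] = (32, 32, 32)
    effect: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 5:
            raise ValueError("n_per_class must be >= 5")
        if self.effect < 0:
            raise ValueError("effect must be >= 0 (0 = null cohort)")


def grating_block(dims) -> tuple[slice, slice, slice]:
    """The fixed sub-block carrying the class signal: the central half per axis."""
    return tuple(slice(s // 4, s // 4 + s // 2) for s in dims)


def generate_volume(class_label: int, spec: CohortSpec, index: int = 0) -> Volume3D:
    """One subject's volume: Gaussian noise, plus the grating for class 1.

    Deterministic per (spec.seed, index).  The grating has amplitude
    ``spec.effect``, direction (1, 1, 0), wavelength 8 voxels and a
    subject-specific uniform random phase, confined to the central
    sub-block.
    """
    rng = np.random.default_rng((spec.seed, int(index)))
    data = rng.normal(0.0, spec.noise_sd, spec.dims) if spec.noise_sd > 0 \
        else np.zeros(spec.dims)
    if class_label == 1 and spec.effect > 0:
        block = grating_block(spec.dims)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        xs = np.arange(block[0].start, block[0].stop)
        ys = np.arange(block[1].start, block[1].stop)
        wave = np.sin(2.0 * np.pi * (xs[:, None] + ys[None, :]) / GRATING_WAVELENGTH
                      + phase)
        data[block] += spec.effect * wave[:, :, None]
    return Volume3D(data)


def generate_cohort_arrays(spec: CohortSpec) -> tuple[list[Volume3D], np.ndarray, list[str]]:
    """In-memory balanced cohort: volumes, labels (0/1) and subject ids.

    Subjects 0..n-1 are class 0 (controls), n..2n-1 class 1.
    """
    volumes, labels, ids = [], [], []
    for index in range(2 * spec.n_per_class):
        label = 0 if index < spec.n_per_class else 1
        volumes.append(generate_volume(label, spec, index))
        labels.append(label)
        ids.append(f"sub-{index:04d}")
    return volumes, np.asarray(labels), ids


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write a balanced cohort to disk: NIfTI volumes plus a label TSV.

    Returns the label table (subject_id, path, label); the TSV is
    byte-identical across re-runs with the same spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volumes, labels, ids = generate_cohort_arrays(spec)
    rows = []
    for vol, label, sid in zip(volumes, labels, ids):
        path = out_dir / f"{sid}.nii.gz"
        write_volume(vol, path)
        rows.append({"subject_id": sid, "path": path.name, "label": int(label)})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    return table


def generate_personal_table(n: int, missing_rate: float = 0.1,
                            seed: int = 0) -> pd.DataFrame:
    """A phenotypic table emulating multi-site cohort metadata.

    Columns: subject_id, age (years), sex (F/M), handedness (signed
    score in [-1, 1]), iq (Wechsler-like, mean 110 sd 13), site (4
    levels), eyestat (open/closed).  Missing values are planted in the
    iq column at ``missing_rate``; ids match a cohort of size ``n``.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    iq = rng.normal(110.0, 13.0, n)
    miss = rng.random(n) < missing_rate
    iq[miss] = np.nan
    table = pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "age": rng.uniform(8.0, 20.0, n).round(1),
        "sex": rng.choice(["F", "M"], n),
        "handedness": np.where(rng.random(n) < 0.9, 1, -1) * rng.uniform(0.1, 1.0, n),
        "iq": iq,
        "site": rng.choice(["siteA", "siteB", "siteC", "siteD"], n),
        "eyestat": rng.choice(["open", "closed"], n),
    })
    return table
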