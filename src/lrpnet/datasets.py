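"""Assembly of the three task-dataset families and the stratified split.

Three dataset families are built from preprocessed window samples:

* longitudinal screening — one binary (0 vs 100 mM) dataset per leaf
  region, pooling all plants and leaf levels;
* hierarchy screening — one binary dataset per leaf level, restricted
  to the previously selected optimal region (one representative leaf
  per plant per level);
* five-gradient recognition — one 5-class dataset at the optimal
  position.

Every dataset is split 80/20 at the window level, stratified by class,
so per-class counts match the balanced design exactly (e.g. the
3600-sample five-gradient dataset splits into 2880/720 with 576/144 per
class).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .preprocess import MATRIX_SIDE, SampleMatrix
from .simulate import (
    ALL_POSITIONS,
    CONCENTRATIONS_MM,
    SCREENING_CONCENTRATIONS_MM,
    LeafLevel,
    PositionLabel,
    Region,
)

__all__ = [
    "LabeledDataset",
    "SplitDataset",
    "build_longitudinal_datasets",
    "build_hierarchy_datasets",
    "build_five_gradient_dataset",
    "stratified_split",
    "IncompleteDesignError",
]

Task = Literal["longitudinal_binary", "hierarchy_binary", "five_gradient"]


class IncompleteDesignError(ValueError):
    """A required (plant, position, concentration) cell has no samples."""


@dataclass
class LabeledDataset:
    """A stack of sample matrices with class labels and metadata.

    ``X`` has shape (N, 1, 30, 30); ``y`` holds NaCl concentrations in
    mM.  ``classes`` is the sorted label set of the task.
    """

    X: np.ndarray
    y: np.ndarray
    plant_ids: list[str]
    positions: list[PositionLabel]
    window_indices: np.ndarray
    task: Task
    grouping_key: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 4 or self.X.shape[1:] != (1, MATRIX_SIDE, MATRIX_SIDE):
            raise ValueError(f"X must be (N, 1, 30, 30), got {self.X.shape}")
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def class_counts(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in sorted(Counter(self.y).items())}

    def subset(self, idx: np.ndarray, grouping_key: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            plant_ids=[self.plant_ids[i] for i in idx],
            positions=[self.positions[i] for i in idx],
            window_indices=self.window_indices[idx],
            task=self.task,
            grouping_key=grouping_key or self.grouping_key,
        )


@dataclass
class SplitDataset:
    """A stratified train/test partition of one dataset."""

    train: LabeledDataset
    test: LabeledDataset
    split_seed: int
    ratio: float = 0.8

    def manifest(self) -> dict:
        return {
            "task": self.train.task,
            "grouping_key": self.train.grouping_key,
            "ratio": self.ratio,
            "split_seed": self.split_seed,
            "n_train": len(self.train),
            "n_test": len(self.test),
            "train_class_counts": self.train.class_counts(),
            "test_class_counts": self.test.class_counts(),
        }


def _stack(
    samples: Sequence[SampleMatrix], task: Task, grouping_key: str
) -> LabeledDataset:
    X = np.stack([s.grid for s in samples])[:, None, :, :]
    return LabeledDataset(
        X=X,
        y=np.array([s.label_mM for s in samples], dtype=np.int64),
        plant_ids=[s.plant_id for s in samples],
        positions=[s.position for s in samples],
        window_indices=np.array([s.window_index for s in samples], dtype=np.int64),
        task=task,
        grouping_key=grouping_key,
    )


def _check_cells(
    samples: Sequence[SampleMatrix],
    plants: Sequence[str],
    positions: Sequence[PositionLabel],
    concentrations: Sequence[int],
) -> None:
    present = {(s.plant_id, s.position, s.label_mM) for s in samples}
    for plant in plants:
        for pos in positions:
            for conc in concentrations:
                if (plant, pos, conc) not in present:
                    raise IncompleteDesignError(
                        f"no samples for plant={plant}, position={pos.key()}, "
                        f"concentration={conc} mM"
                    )


def build_longitudinal_datasets(
    samples: Sequence[SampleMatrix],
) -> dict[Region, LabeledDataset]:
    """One binary (0 vs 100 mM) dataset per leaf region, pooling plants and levels.

    With the full screening design (3 plants x 3 leaves x 2 concentrations
    x 240 windows) each regional dataset holds 4320 samples and the three
    together 12,960.
    """
    if not samples:
        raise IncompleteDesignError("no samples provided")
    plants = sorted({s.plant_id for s in samples})
    screening = [s for s in samples if s.label_mM in SCREENING_CONCENTRATIONS_MM]
    _check_cells(screening, plants, ALL_POSITIONS, SCREENING_CONCENTRATIONS_MM)
    out: dict[Region, LabeledDataset] = {}
    for region in Region:
        sel = [s for s in screening if s.position.region == region]
        out[region] = _stack(sel, "longitudinal_binary", region.value)
    return out


def build_hierarchy_datasets(
    samples: Sequence[SampleMatrix], optimal_region: Region
) -> dict[LeafLevel, LabeledDataset]:
    """One binary dataset per leaf level, restricted to the optimal region.

    Each level keeps one representative leaf per plant (the study design
    records exactly one leaf per plant-level cell), giving 1440 samples
    per dataset under the full design.
    """
    if not samples:
        raise IncompleteDesignError("no samples provided")
    plants = sorted({s.plant_id for s in samples})
    screening = [
        s
        for s in samples
        if s.label_mM in SCREENING_CONCENTRATIONS_MM
        and s.position.region == optimal_region
    ]
    positions = [PositionLabel(lv, optimal_region) for lv in LeafLevel]
    _check_cells(screening, plants, positions, SCREENING_CONCENTRATIONS_MM)
    out: dict[LeafLevel, LabeledDataset] = {}
    for level in LeafLevel:
        sel = [s for s in screening if s.position.leaf_level == level]
        out[level] = _stack(
            sel, "hierarchy_binary", f"{level.value}-{optimal_region.value}"
        )
    return out


def build_five_gradient_dataset(
    samples: Sequence[SampleMatrix], optimal_position: PositionLabel
) -> LabeledDataset:
    """The 5-class dataset at the optimal position (3600 samples, 720/class
    under the full design)."""
    if not samples:
        raise IncompleteDesignError("no samples provided")
    sel = [s for s in samples if s.position == optimal_position]
    plants = sorted({s.plant_id for s in sel})
    if not plants:
        raise IncompleteDesignError(
            f"no samples at position {optimal_position.key()}"
        )
    _check_cells(sel, plants, [optimal_position], CONCENTRATIONS_MM)
    return _stack(sel, "five_gradient", optimal_position.key())


def stratified_split(
    dataset: LabeledDataset, ratio: float = 0.8, seed: int = 0
) -> SplitDataset:
    """Random class-stratified split, deterministic under ``seed``.

    When class counts are divisible by the ratio denominator (true for
    all study designs here) the per-class train/test counts are exact.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=ratio,
        stratify=dataset.y,
        random_state=int(seed) % (2**32),
        shuffle=True,
    )
    return SplitDataset(
        train=dataset.subset(np.sort(train_idx)),
        test=dataset.subset(np.sort(test_idx)),
        split_seed=int(seed),
        ratio=ratio,
    )


def write_manifest(split: SplitDataset, path: str | Path) -> None:
    """JSON audit manifest of one split (counts, seed, grouping key)."""
    Path(path).write_text(json.dumps(split.manifest(), indent=2))
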