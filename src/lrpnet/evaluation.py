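"""Training/evaluation protocol, metrics, position screening and ablation.

Models are trained with Adam on a fixed stratified split and scored on
the held-out windows with Accuracy, macro Precision, macro Recall and
Cohen's kappa.  Each configuration is run several times with different
initialization/shuffling seeds on the same split, and the mean and
sample standard deviation per metric are reported.

The spatial screening is stepwise: first the three longitudinal-region
binary datasets are compared and the region with the highest mean
accuracy wins; then, within that region, the three leaf-level datasets
are compared the same way.  Ties break by mean kappa, then by lower
mean final training loss, then lexicographically by candidate key.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_score,
    recall_score,
)

from .datasets import (
    LabeledDataset,
    SplitDataset,
    build_hierarchy_datasets,
    build_longitudinal_datasets,
    stratified_split,
)
from .model import LRPNetClassifier
from .preprocess import SampleMatrix
from .simulate import LeafLevel, PositionLabel, Region

__all__ = [
    "TrainConfig",
    "Metrics",
    "RunSummary",
    "ScreeningResult",
    "compute_metrics",
    "train_model",
    "evaluate_model",
    "repeat_runs",
    "screen_positions",
    "run_two_stage_screening",
    "run_ablation",
]

METRIC_NAMES = ("accuracy", "precision_macro", "recall_macro", "kappa")


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the study protocol)."""

    learning_rate: float = 1e-4
    batch_size: int = 30
    epochs: int = 200
    seed: int = 0
    n_runs: int = 5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass
class Metrics:
    """The four evaluation metrics plus the confusion matrix."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    kappa: float
    confusion_matrix: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in METRIC_NAMES}


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    labels: Sequence[int] | None = None,
) -> Metrics:
    """Accuracy, macro precision/recall and Cohen's kappa.

    ``labels`` fixes the class set (and confusion-matrix order); by
    default it is the sorted union of truth and prediction.  A class
    absent from both contributes precision/recall 0 with a warning.
    If the expected agreement p_e equals 1 (both sequences constant and
    equal) kappa is defined as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("cannot compute metrics on empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = np.asarray(labels)
    present = np.union1d(np.unique(y_true), np.unique(y_pred))
    absent = np.setdiff1d(labels, present)
    if len(absent) > 0:
        warnings.warn(
            f"classes {absent.tolist()} absent from truth and prediction; "
            "their precision/recall contribute 0 to the macro average",
            UserWarning,
            stacklevel=2,
        )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    total = cm.sum()
    p_o = float(np.trace(cm)) / total
    p_e = float(cm.sum(axis=1) @ cm.sum(axis=0)) / total**2
    kappa = 0.0 if p_e == 1.0 else float(
        cohen_kappa_score(y_true, y_pred, labels=labels)
    )
    return Metrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision_macro=float(
            precision_score(y_true, y_pred, labels=labels, average="macro",
                            zero_division=0)
        ),
        recall_macro=float(
            recall_score(y_true, y_pred, labels=labels, average="macro",
                         zero_division=0)
        ),
        kappa=kappa,
        confusion_matrix=cm,
    )


ModelFactory = Callable[[int], LRPNetClassifier]


def _default_factory(
    train_config: TrainConfig, **arch_kwargs
) -> ModelFactory:
    def factory(seed: int) -> LRPNetClassifier:
        return LRPNetClassifier(
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            epochs=train_config.epochs,
            random_state=seed,
            **arch_kwargs,
        )

    return factory


def train_model(
    split: SplitDataset,
    train_config: TrainConfig | None = None,
    seed: int | None = None,
    model_factory: ModelFactory | None = None,
    **arch_kwargs,
) -> tuple[LRPNetClassifier, dict]:
    """Fit one classifier on the training partition of a split.

    Returns the fitted estimator and its training log (per-epoch loss
    and training accuracy).  ``arch_kwargs`` forward to
    :class:`LRPNetClassifier` (e.g. ``use_poolformer=False``).
    """
    train_config = train_config or TrainConfig()
    seed = train_config.seed if seed is None else seed
    factory = model_factory or _default_factory(train_config, **arch_kwargs)
    clf = factory(seed)
    X = split.train.X.reshape(len(split.train), -1)
    clf.fit(X, split.train.y)
    log = {
        "loss_curve": list(clf.loss_curve_),
        "train_accuracy_curve": list(clf.train_accuracy_curve_),
        "seed": seed,
    }
    return clf, log


def evaluate_model(clf: LRPNetClassifier, dataset: LabeledDataset) -> Metrics:
    """Score a fitted classifier on a labelled dataset."""
    X = dataset.X.reshape(len(dataset), -1)
    y_pred = clf.predict(X)
    return compute_metrics(dataset.y, y_pred, labels=clf.classes_)


@dataclass
class RunSummary:
    """Per-run metrics with mean and sample SD aggregation.

    ``final_train_losses`` keeps the last-epoch training loss of each
    run; screening uses it as a continuous tie-breaker.
    """

    runs: list[Metrics]
    seeds: list[int]
    final_train_losses: list[float] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.runs]))

    def sd(self, metric: str) -> float | None:
        """Sample standard deviation (ddof=1); None for a single run."""
        if self.n_runs < 2:
            return None
        return float(np.std([getattr(m, metric) for m in self.runs], ddof=1))

    def mean_final_train_loss(self) -> float:
        if not self.final_train_losses:
            return float("nan")
        return float(np.mean(self.final_train_losses))

    def as_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "seeds": self.seeds,
            "mean": {m: self.mean(m) for m in METRIC_NAMES},
            "sd": {m: self.sd(m) for m in METRIC_NAMES},
            "final_train_losses": self.final_train_losses,
            "runs": [m.as_dict() for m in self.runs],
        }


def repeat_runs(
    split: SplitDataset,
    train_config: TrainConfig | None = None,
    n_runs: int | None = None,
    model_factory: ModelFactory | None = None,
    **arch_kwargs,
) -> RunSummary:
    """Train and evaluate ``n_runs`` times on the same fixed split.

    Run ``i`` uses seed ``train_config.seed + i`` for initialization and
    shuffling; the split itself is never re-randomized.
    """
    train_config = train_config or TrainConfig()
    n_runs = train_config.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs, seeds, losses = [], [], []
    for i in range(n_runs):
        seed = train_config.seed + i
        clf, log = train_model(
            split, train_config, seed=seed, model_factory=model_factory,
            **arch_kwargs,
        )
        runs.append(evaluate_model(clf, split.test))
        seeds.append(seed)
        if log["loss_curve"]:
            losses.append(log["loss_curve"][-1])
    return RunSummary(runs=runs, seeds=seeds, final_train_losses=losses)


Stage = Literal["longitudinal", "hierarchy"]


@dataclass
class ScreeningResult:
    """Outcome of one screening stage over its candidate positions."""

    stage: Stage
    per_candidate: dict[str, RunSummary]
    winner: str
    decision_rule: str = (
        "max mean accuracy; ties by mean kappa, then lower mean final "
        "training loss, then lexicographic key"
    )

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "winner": self.winner,
            "decision_rule": self.decision_rule,
            "candidates": {k: v.as_dict() for k, v in self.per_candidate.items()},
        }


def _select_winner(per_candidate: dict[str, RunSummary]) -> str:
    # test accuracy and kappa are discrete on small test sets; the final
    # training loss is continuous, so exact ties essentially never reach
    # the lexicographic fallback
    return min(
        sorted(per_candidate),
        key=lambda k: (
            -per_candidate[k].mean("accuracy"),
            -per_candidate[k].mean("kappa"),
            per_candidate[k].mean_final_train_loss(),
            k,
        ),
    )


def screen_positions(
    samples: Sequence[SampleMatrix],
    stage: Stage,
    train_config: TrainConfig | None = None,
    n_runs: int | None = None,
    model_factory: ModelFactory | None = None,
    optimal_region: Region | None = None,
    split_seed: int = 0,
    **arch_kwargs,
) -> ScreeningResult:
    """Run one screening stage on preprocessed screening-study samples.

    The longitudinal stage compares the three region datasets; the
    hierarchy stage requires ``optimal_region`` (the longitudinal
    winner) and compares the three leaf-level datasets within it.
    """
    train_config = train_config or TrainConfig()
    if stage == "longitudinal":
        candidates = {
            region.value: ds
            for region, ds in build_longitudinal_datasets(samples).items()
        }
    elif stage == "hierarchy":
        if optimal_region is None:
            raise ValueError("hierarchy stage requires optimal_region")
        candidates = {
            level.value: ds
            for level, ds in build_hierarchy_datasets(samples, optimal_region).items()
        }
    else:
        raise ValueError(f"unknown stage {stage!r}")
    per_candidate = {}
    for key in sorted(candidates):
        split = stratified_split(candidates[key], seed=split_seed)
        per_candidate[key] = repeat_runs(
            split, train_config, n_runs=n_runs, model_factory=model_factory,
            **arch_kwargs,
        )
    return ScreeningResult(
        stage=stage,
        per_candidate=per_candidate,
        winner=_select_winner(per_candidate),
    )


def run_two_stage_screening(
    samples: Sequence[SampleMatrix],
    train_config: TrainConfig | None = None,
    n_runs: int | None = None,
    model_factory: ModelFactory | None = None,
    split_seed: int = 0,
    **arch_kwargs,
) -> tuple[ScreeningResult, ScreeningResult, PositionLabel]:
    """Longitudinal screening, then hierarchy screening within the winner.

    Returns both stage results and the selected optimal position.
    """
    longitudinal = screen_positions(
        samples, "longitudinal", train_config, n_runs, model_factory,
        split_seed=split_seed, **arch_kwargs,
    )
    region = Region(longitudinal.winner)
    hierarchy = screen_positions(
        samples, "hierarchy", train_config, n_runs, model_factory,
        optimal_region=region, split_seed=split_seed, **arch_kwargs,
    )
    level = LeafLevel(hierarchy.winner)
    return longitudinal, hierarchy, PositionLabel(level, region)


#: The ablation grid: PoolFormer-only, ECA-only, both (the reported rows)
#: plus the neither-module control for a complete factorial.
ABLATION_VARIANTS: tuple[tuple[bool, bool], ...] = (
    (True, False),
    (False, True),
    (True, True),
    (False, False),
)


def run_ablation(
    split: SplitDataset,
    train_config: TrainConfig | None = None,
    n_runs: int | None = None,
    variants: Sequence[tuple[bool, bool]] = ABLATION_VARIANTS,
) -> dict[tuple[bool, bool], RunSummary]:
    """Evaluate (use_poolformer, use_eca) variants under one protocol."""
    out: dict[tuple[bool, bool], RunSummary] = {}
    for use_pf, use_eca in variants:
        out[(use_pf, use_eca)] = repeat_runs(
            split, train_config, n_runs=n_runs,
            use_poolformer=use_pf, use_eca=use_eca,
        )
    return out


def ablation_table(results: Mapping[tuple[bool, bool], RunSummary]) -> str:
    """Render the ablation report (mean +/- SD per metric, one variant per row)."""
    header = f"{'poolformer':<11}{'eca':<5}" + "".join(
        f"{m:<22}" for m in METRIC_NAMES
    )
    lines = [header]
    for (pf, eca), summary in results.items():
        cells = []
        for m in METRIC_NAMES:
            sd = summary.sd(m)
            sd_txt = f" +/- {sd:.4f}" if sd is not None else ""
            cells.append(f"{summary.mean(m):.4f}{sd_txt:<14}")
        lines.append(
            f"{'yes' if pf else 'no':<11}{'yes' if eca else 'no':<5}"
            + "".join(f"{c:<22}" for c in cells)
        )
    return "\n".join(lines)


def write_runs_csv(summary: RunSummary, path: str | Path) -> None:
    """One CSV row per run with the four metrics."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["run", "seed", *METRIC_NAMES])
        for i, (m, seed) in enumerate(zip(summary.runs, summary.seeds)):
            writer.writerow([i, seed] + [getattr(m, name) for name in METRIC_NAMES])


def write_summary_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
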