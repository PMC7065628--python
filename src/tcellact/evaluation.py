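"""Donor-wise nested cross-validation and imbalance-aware evaluation.

The evaluation scheme is leave-one-donor-out at both levels: for each
outer test donor, an inner loop cross-validates every hyper-parameter
configuration across the remaining donors (each serving once as the
validation donor), selects the configuration with the highest mean average
precision, refits on all inner donors and evaluates once on the test
donor.  With five donors in play this is the 5 x 4 nested scheme; one
donor can additionally be held out of everything as a final
generalization test.

Leakage control is explicit: augmented image copies may appear only in
training portions — validation, test and early-stopping sets contain
original images only — and every donor-access event is recorded in an
audit log so the holdout invariant can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score,
                             precision_recall_curve, roc_auc_score,
                             roc_curve)

from .backbone import BackboneSpec, MiniBackbone, backbone_prepare
from .features import build_feature_table
from .models import make_model
from .preprocess import ProcessedCell

__all__ = [
    "CellDataset",
    "SplitPlan",
    "MetricReport",
    "GridResult",
    "make_outer_splits",
    "make_early_stop_split",
    "compute_metrics",
    "grid_search",
    "run_nested_cv",
    "holdout_final_test",
]


class CellDataset:
    """Processed-cell collection: image stack, masks, per-cell metadata.

    ``meta`` columns: cell_id (index), donor_id, label, augmentation_tag,
    source_id.  An audit log records every donor-access event issued by the
    evaluation routines.
    """

    def __init__(self, images: np.ndarray, meta: pd.DataFrame,
                 masks: np.ndarray | None = None):
        if len(images) != len(meta):
            raise ValueError("images and meta length mismatch")
        self.images = images
        self.masks = masks
        self.meta = meta.reset_index(drop=True)
        self.audit_log: list[dict] = []
        self._feature_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_processed(cls, cells: list[ProcessedCell]) -> "CellDataset":
        images = np.stack([c.image for c in cells])
        masks = (np.stack([c.mask for c in cells])
                 if all(c.mask is not None for c in cells) else None)
        meta = pd.DataFrame({
            "donor_id": [c.donor_id for c in cells],
            "label": [c.label for c in cells],
            "augmentation_tag": [c.augmentation_tag for c in cells],
            "source_id": [c.source_id or f"cell{i:05d}"
                          for i, c in enumerate(cells)],
        })
        return cls(images, meta, masks)

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def donors(self) -> list[str]:
        return sorted(self.meta["donor_id"].unique())

    @property
    def y(self) -> np.ndarray:
        return (self.meta["label"] == "activated").to_numpy(dtype=int)

    def rows(self, donors=None, original_only: bool = False) -> np.ndarray:
        """Row indices for the given donors (all if None)."""
        m = np.ones(len(self.meta), dtype=bool)
        if donors is not None:
            m &= self.meta["donor_id"].isin(list(donors)).to_numpy()
        if original_only:
            m &= (self.meta["augmentation_tag"] == "original").to_numpy()
        return np.nonzero(m)[0]

    def log(self, event: str, donors, **extra) -> None:
        self.audit_log.append({"event": event,
                               "donors": sorted(set(donors)), **extra})

    def features(self, feature_set_id: str) -> np.ndarray:
        """Whole-dataset feature matrix for one feature set (cached)."""
        if feature_set_id not in self._feature_cache:
            cells = [ProcessedCell(
                image=self.images[i],
                donor_id=self.meta.at[i, "donor_id"],
                label=self.meta.at[i, "label"],
                augmentation_tag=self.meta.at[i, "augmentation_tag"],
                source_id=f"r{i:06d}",
                mask=None if self.masks is None else self.masks[i])
                for i in range(len(self))]
            table = build_feature_table(cells, feature_set_id)
            self._feature_cache[feature_set_id] = table.X
        return self._feature_cache[feature_set_id]


@dataclass
class SplitPlan:
    """One outer fold of the nested scheme."""

    outer_test_donor: str
    inner_folds: list[tuple[tuple[str, ...], str]]  # (train donors, val)
    holdout_donor: str | None = None
    early_stop_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for train, val in self.inner_folds:
            members = set(train) | {val}
            if self.outer_test_donor in members:
                raise ValueError("test donor leaks into an inner fold")
            if self.holdout_donor is not None and self.holdout_donor in members:
                raise ValueError("holdout donor leaks into an inner fold")
            if val in train:
                raise ValueError("validation donor appears in training")

    @property
    def training_donors(self) -> list[str]:
        return sorted({d for train, val in self.inner_folds
                       for d in (*train, val)})


def make_outer_splits(donors: list[str],
                      holdout_donor: str | None = None) -> list[SplitPlan]:
    """One plan per non-holdout donor; each plan's inner loop rotates the
    validation donor over the remaining non-holdout donors."""
    pool = [d for d in donors if d != holdout_donor]
    if len(pool) < 3:
        raise ValueError("nested cross-validation needs >= 3 donors")
    plans = []
    for test in pool:
        inner_pool = [d for d in pool if d != test]
        folds = [(tuple(d for d in inner_pool if d != val), val)
                 for val in inner_pool]
        plans.append(SplitPlan(outer_test_donor=test, inner_folds=folds,
                               holdout_donor=holdout_donor))
    return plans


def make_early_stop_split(dataset: CellDataset, train_rows: np.ndarray,
                          seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Carve an early-stopping set out of a training row set.

    One-fourth of the unaugmented source cells are sampled; their original
    rows form the early-stopping set and ALL their copies (original and
    augmented) are removed from training."""
    meta = dataset.meta.iloc[train_rows]
    orig = meta[meta["augmentation_tag"] == "original"]
    if orig.empty:
        raise ValueError("training set has no unaugmented cells")
    sources = np.sort(orig["source_id"].unique())
    rng = np.random.default_rng(seed)
    n_early = max(1, int(round(len(sources) * 0.25)))
    chosen = set(rng.choice(sources, size=n_early, replace=False))
    es_mask = (orig["source_id"].isin(chosen)).to_numpy()
    early_rows = train_rows[
        np.isin(train_rows, orig.index.to_numpy()[es_mask])]
    keep = ~meta["source_id"].isin(chosen).to_numpy()
    return train_rows[keep], early_rows


@dataclass
class MetricReport:
    """Confusion counts at threshold 0.5 plus threshold-free curves."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    auc: float
    average_precision: float
    roc_points: np.ndarray      # (k, 2) FPR, TPR
    pr_points: np.ndarray       # (k, 2) recall, precision
    curves_defined: bool = True
    n: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "accuracy", "precision", "recall",
                 "auc", "average_precision", "n")}


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricReport:
    """All evaluation metrics for one score set.

    Thresholded metrics classify ``score >= threshold`` as positive; AUC
    summarizes the ROC curve (trapezoidal) and average precision the PR
    curve (stepwise sum).  With a single-class label set the curve metrics
    are undefined (NaN) and flagged via ``curves_defined=False``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = len(labels)
    accuracy = (tp + tn) / n if n else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0

    if labels.min() == labels.max():
        return MetricReport(tp, fp, tn, fn, accuracy, precision, recall,
                            float("nan"), float("nan"),
                            np.empty((0, 2)), np.empty((0, 2)),
                            curves_defined=False, n=n)
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return MetricReport(
        tp, fp, tn, fn, accuracy, precision, recall,
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
        np.column_stack([fpr, tpr]),
        np.column_stack([rec[::-1], prec[::-1]]), n=n)


@dataclass
class GridResult:
    configs: list[dict]
    mean_ap: list[float]
    selected: dict
    selected_index: int
    per_fold_ap: list[list[float]]


class _ModelData:
    """Precomputed model inputs for one dataset and model kind."""

    FEATURE_SETS = {"lasso_pixels": "pixels6724", "lasso_scalar": "scalar2",
                    "lasso_cp": "cp123", "mlp": "pixels6724"}

    def __init__(self, dataset: CellDataset, model_kind: str,
                 backbone: MiniBackbone | None = None):
        self.dataset = dataset
        self.model_kind = model_kind
        self.backbone = backbone
        if model_kind in self.FEATURE_SETS:
            self._X = dataset.features(self.FEATURE_SETS[model_kind])
        elif model_kind == "lenet":
            self._X = dataset.images.astype(float)
        elif model_kind in ("pretrained_offshelf", "pretrained_finetune"):
            bb = backbone or MiniBackbone()
            self.backbone = bb
            prepared = backbone_prepare(dataset.images, bb.spec)
            if model_kind == "pretrained_offshelf":
                # final-layer feature maps from the fully frozen backbone
                self._X = bb.forward_modules(prepared)
            else:
                self._X = prepared
        else:  # frequency: inputs are ignored
            self._X = np.zeros((len(dataset), 1))

    def X(self, rows: np.ndarray) -> np.ndarray:
        return self._X[rows]

    def needs_early_stop(self) -> bool:
        return self.model_kind in ("mlp", "lenet", "pretrained_offshelf",
                                   "pretrained_finetune")

    def build(self, config: dict):
        config = dict(config)
        if self.model_kind in ("pretrained_offshelf", "pretrained_finetune"):
            config.setdefault("backbone", self.backbone)
        return make_model(self.model_kind, config)


def _fit_on(md: _ModelData, dataset: CellDataset, config: dict,
            train_rows: np.ndarray, seed: int):
    y = dataset.y
    if md.needs_early_stop():
        train_rows, early_rows = make_early_stop_split(
            dataset, train_rows, seed)
        model = md.build(config)
        model.fit(md.X(train_rows), y[train_rows],
                  early_stop=(md.X(early_rows), y[early_rows]))
    else:
        model = md.build(config)
        model.fit(md.X(train_rows), y[train_rows])
    return model


def grid_search(plan: SplitPlan, grid: list[dict], dataset: CellDataset,
                model_kind: str, seed: int = 0,
                md: _ModelData | None = None) -> GridResult:
    """Inner-loop grid search for one outer plan.

    Each configuration trains on every inner fold's training donors
    (augmented rows) and is scored by average precision on the validation
    donor's original rows; selection is by highest mean AP with ties going
    to the earlier-listed configuration."""
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    md = md or _ModelData(dataset, model_kind)
    for config in grid:  # validate configs before any training
        md.build(config)
    y = dataset.y
    per_fold_ap: list[list[float]] = []
    for ci, config in enumerate(grid):
        aps = []
        for fi, (train_donors, val_donor) in enumerate(plan.inner_folds):
            train_rows = dataset.rows(train_donors)
            val_rows = dataset.rows([val_donor], original_only=True)
            dataset.log("inner_train", train_donors,
                        test_donor=plan.outer_test_donor)
            dataset.log("inner_validate", [val_donor],
                        test_donor=plan.outer_test_donor)
            model = _fit_on(md, dataset, config, train_rows,
                            seed=seed * 1009 + ci * 31 + fi)
            scores = model.score01(md.X(val_rows))
            if y[val_rows].min() == y[val_rows].max():
                raise ValueError(
                    f"validation donor {val_donor} is single-class; "
                    "average precision undefined")
            aps.append(float(average_precision_score(y[val_rows], scores)))
        per_fold_ap.append(aps)
    mean_ap = [float(np.mean(a)) for a in per_fold_ap]
    best = int(np.argmax(mean_ap))  # argmax returns the first maximum
    return GridResult(configs=list(grid), mean_ap=mean_ap,
                      selected=grid[best], selected_index=best,
                      per_fold_ap=per_fold_ap)


def run_nested_cv(dataset: CellDataset, model_kind: str, grid: list[dict],
                  holdout_donor: str | None = None, seed: int = 0,
                  backbone: MiniBackbone | None = None) -> dict:
    """Full nested cross-validation for one model kind.

    Returns ``{"per_donor": {donor: MetricReport}, "grid": {donor:
    GridResult}, "summary": DataFrame, "models": {donor: estimator}}``.
    Test evaluation always uses the test donor's original (unaugmented)
    rows and a model that never saw that donor."""
    plans = make_outer_splits(dataset.donors, holdout_donor)
    md = _ModelData(dataset, model_kind, backbone)
    per_donor: dict[str, MetricReport] = {}
    grids: dict[str, GridResult] = {}
    models: dict[str, object] = {}
    ss = np.random.SeedSequence(seed)
    plan_seeds = [int(c.generate_state(1)[0] % (2**31))
                  for c in ss.spawn(len(plans))]
    for plan, pseed in zip(plans, plan_seeds):
        gr = grid_search(plan, grid, dataset, model_kind, seed=pseed, md=md)
        train_donors = plan.training_donors
        assert plan.outer_test_donor not in train_donors
        train_rows = dataset.rows(train_donors)
        dataset.log("outer_train", train_donors,
                    test_donor=plan.outer_test_donor)
        model = _fit_on(md, dataset, gr.selected, train_rows, seed=pseed)
        test_rows = dataset.rows([plan.outer_test_donor], original_only=True)
        dataset.log("outer_test", [plan.outer_test_donor])
        scores = model.score01(md.X(test_rows))
        per_donor[plan.outer_test_donor] = compute_metrics(
            scores, dataset.y[test_rows])
        grids[plan.outer_test_donor] = gr
        models[plan.outer_test_donor] = model
    rows = [{"donor": d, **r.to_dict()} for d, r in per_donor.items()]
    summary = pd.DataFrame(rows).set_index("donor")
    summary.loc["mean"] = summary.mean(numeric_only=True)
    return {"per_donor": per_donor, "grid": grids, "summary": summary,
            "models": models}


def holdout_final_test(dataset: CellDataset, holdout_donor: str,
                       model_kind: str, grid: list[dict],
                       seed: int = 0,
                       backbone: MiniBackbone | None = None) -> dict:
    """Final generalization test on a donor untouched so far.

    Verifies from the audit log that the holdout donor was never used in
    any prior training or validation event, then applies the same nested
    scheme with the holdout as the test donor: inner loop over all other
    donors, selection by mean AP, refit on all of them, one evaluation on
    the holdout's original rows."""
    for event in dataset.audit_log:
        if event["event"] != "outer_test" and \
                holdout_donor in event["donors"]:
            raise RuntimeError(
                f"holdout donor {holdout_donor} was accessed earlier: "
                f"{event}")
    pool = [d for d in dataset.donors if d != holdout_donor]
    if len(pool) < 2:
        raise ValueError("need >= 2 non-holdout donors")
    folds = [(tuple(d for d in pool if d != val), val) for val in pool]
    plan = SplitPlan(outer_test_donor=holdout_donor, inner_folds=folds)
    md = _ModelData(dataset, model_kind, backbone)
    gr = grid_search(plan, grid, dataset, model_kind, seed=seed, md=md)
    train_rows = dataset.rows(pool)
    dataset.log("outer_train", pool, test_donor=holdout_donor)
    model = _fit_on(md, dataset, gr.selected, train_rows, seed=seed)
    test_rows = dataset.rows([holdout_donor], original_only=True)
    dataset.log("outer_test", [holdout_donor])
    scores = model.score01(md.X(test_rows))
    report = compute_metrics(scores, dataset.y[test_rows])
    return {"report": report, "grid": gr, "model": model}
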