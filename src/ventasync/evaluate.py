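"""Partial-dropping k-fold cross-validation, metrics and the retention sweep.

The protocol: split the dataset into k folds; for each fold the remaining
k-1 folds form the training pool M, of which only a random subset M1 of
size floor(PRR * |M|) is retained (PRR = partial retention rate) and the
rest (M2) is dropped.  The model trains on M1 (70% train / 30%
validation) and is scored on the untouched test fold.  Sweeping PRR maps
out how performance degrades as labeled data becomes scarce.

Metrics follow the convention used here throughout: accuracy,
sensitivity, specificity, and an F1 defined as the harmonic mean of
sensitivity and specificity (not the precision-recall F1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as md
from .classify import (SVMHead, build_recurrent_baseline, cycle_to_sequence,
                       fit_svm_head, handcrafted_features)
from .nn.train import TrainingConfig, fit
from .preprocess import images_to_array, record_to_images
from .synth import LABEL_OTHER, WaveformRecord

ARCH_SHORT = {"Tiny": "tiny_cnn", "Mobile": "mobilenet_v1",
              "VGG": "vgg16_bn", "InceRes": "inception_resnet_v2"}


@dataclass
class FoldPlan:
    """One partial-dropping CV assignment over example ids."""

    k: int
    prr: float
    seed: int
    fold_assignments: dict                     # id -> fold index
    folds: list = field(default_factory=list)  # per fold: dict with sets

    def fold(self, i: int) -> dict:
        return self.folds[i]


def make_partial_dropping_folds(ids, k: int, prr: float, seed: int = 0,
                                labels=None, int_mode: str = "floor") -> FoldPlan:
    """Random equal-as-possible k folds with per-fold M1/M2 retention split.

    ``labels`` (optional, aligned with ids) stratifies the M1 subsample by
    class so extreme retention rates cannot produce single-class training
    sets.  ``int_mode`` selects how i = PRR*|M| is truncated to an
    integer (floor by default).
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if not 2 <= k <= len(ids):
        raise ValueError("need |ids| >= k >= 2")
    if not 0 < prr <= 1:
        raise ValueError("prr must lie in (0, 1]")
    trunc = math.floor if int_mode == "floor" else round
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(i % k) for i, j in enumerate(order)}
    lab = dict(zip(ids, labels)) if labels is not None else None

    folds = []
    for f in range(k):
        test = [i for i in ids if assignment[i] == f]
        pool = [i for i in ids if assignment[i] != f]
        n1 = int(trunc(prr * len(pool)))
        if n1 < 2:
            raise ValueError(
                f"retained set would have {n1} < 2 examples "
                f"(prr={prr}, |M|={len(pool)}): cannot split 70/30")
        if lab is None:
            keep = rng.choice(len(pool), size=n1, replace=False)
            m1 = [pool[j] for j in sorted(keep)]
        else:
            m1 = _stratified_subset(pool, [lab[i] for i in pool], n1, rng)
        m1_set = set(m1)
        folds.append({"test_ids": test, "M_ids": pool, "M1_ids": m1,
                      "M2_ids": [i for i in pool if i not in m1_set]})
    return FoldPlan(k=k, prr=prr, seed=seed, fold_assignments=assignment,
                    folds=folds)


def _stratified_subset(pool, pool_labels, n1, rng):
    """Proportional per-class subsample, guaranteeing >= 1 per class."""
    pool_labels = np.asarray(pool_labels)
    classes = np.unique(pool_labels)
    out = []
    remaining = n1
    for ci, cls in enumerate(classes):
        members = [p for p, l in zip(pool, pool_labels) if l == cls]
        left = len(classes) - ci - 1
        quota = max(1, int(round(n1 * len(members) / len(pool))))
        quota = min(quota, remaining - left, len(members))
        take = rng.choice(len(members), size=max(quota, 0), replace=False)
        out.extend(members[j] for j in sorted(take))
        remaining -= quota
    # top up rounding shortfalls from unused pool members
    if remaining > 0:
        unused = [p for p in pool if p not in set(out)]
        take = rng.choice(len(unused), size=remaining, replace=False)
        out.extend(unused[j] for j in sorted(take))
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return ConfusionCounts(
            tp=int(np.sum(y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            fn=int(np.sum(y_true & ~y_pred)))


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    counts: ConfusionCounts
    model_name: str = ""
    prr: float = 1.0
    fold: int = 0
    seed: int = 0


def compute_metrics(counts: ConfusionCounts, **context) -> MetricsReport:
    """Accuracy, sensitivity, specificity and their harmonic-mean F1.

    Undefined ratios (no positives, or no negatives, in the evaluated
    set) are reported as NaN rather than silently zero.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.tp + counts.tn) / counts.total
    sen = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spe = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    if np.isnan(sen) or np.isnan(spe) or (sen + spe) == 0:
        f1 = float("nan") if np.isnan(sen) or np.isnan(spe) else 0.0
    else:
        f1 = 2 * sen * spe / (sen + spe)
    return MetricsReport(accuracy=acc, sensitivity=sen, specificity=spe,
                         f1=f1, counts=counts, **context)


# ---------------------------------------------------------------------------
# model zoo dispatch

def parse_model_name(name: str) -> dict:
    """Decode a zoo name: {Pr|Rd}_{Tiny|Mobile|VGG|InceRes}_{DC|SVM},
    Manual_SVM, or LSTM."""
    if name == "Manual_SVM":
        return {"kind": "manual_svm"}
    if name == "LSTM":
        return {"kind": "lstm"}
    parts = name.split("_")
    if (len(parts) == 3 and parts[0] in ("Pr", "Rd")
            and parts[1] in ARCH_SHORT and parts[2] in ("DC", "SVM")):
        return {"kind": "cnn", "pretrained": parts[0] == "Pr",
                "arch": ARCH_SHORT[parts[1]], "head": parts[2]}
    raise ValueError(f"unknown model name {name!r}")


def zoo_model_names(archs=("Mobile", "VGG", "InceRes")) -> list:
    """All constructible zoo configurations (12 CNN variants + 2 baselines
    with the published trunks)."""
    names = [f"{init}_{a}_{head}" for init in ("Pr", "Rd")
             for a in archs for head in ("DC", "SVM")]
    return names + ["Manual_SVM", "LSTM"]


# ---------------------------------------------------------------------------
# retention sweep harness

def binary_task_arrays(record: WaveformRecord, pos_label: str) -> dict:
    """Images/sequences/handcrafted features for one-vs-OTHER detection.

    Cycles of the other asynchrony class are excluded, matching the
    separate DT-vs-OTHER and IEE-vs-OTHER evaluations.
    """
    keep = [c for c in record.cycles if c.label in (pos_label, LABEL_OTHER)]
    images = record_to_images(record)
    by_id = {im.cycle_id: im for im in images}
    x_img, _ = images_to_array([by_id[c.cycle_id] for c in keep])
    return {
        "ids": [c.cycle_id for c in keep],
        "y": np.array([1 if c.label == pos_label else 0 for c in keep]),
        "images": x_img,
        "sequences": np.stack([cycle_to_sequence(c) for c in keep]),
        "handcrafted": np.stack([handcrafted_features(c) for c in keep]),
    }


def _head_config(seed: int, max_epochs: int = 60) -> TrainingConfig:
    return TrainingConfig(max_epochs=max_epochs, initial_lr=1e-2,
                          patience_epochs=10, stop_after_reductions=1,
                          seed=seed)


def _extractor_for(arch: str, pretrained: bool, seed: int, cache: dict,
                   pretrain_epochs: int = 10, pretrain_n: int = 40):
    key = (arch, pretrained, seed)
    if key not in cache:
        spec = md.FeatureExtractorSpec(arch)
        if pretrained:
            cfg = TrainingConfig(max_epochs=pretrain_epochs, patience_epochs=3,
                                 stop_after_reductions=1, seed=seed)
            extractor, _ = md.pretrain_source_task(spec, cfg,
                                                   n_per_class=pretrain_n)
        else:
            extractor = md.build_extractor_raw(arch, seed)
        cache[key] = extractor
    return cache[key]


def run_prr_experiment(dataset: WaveformRecord, model_names, prrs, k: int = 5,
                       seeds=(0,), pos_label: str = "DT",
                       head_epochs: int = 60, pretrain_epochs: int = 10,
                       pretrain_n: int = 40, lstm_units: int = 16,
                       datasets_by_seed: dict | None = None) -> pd.DataFrame:
    """Cross-validated metrics for each (model, PRR, fold, seed) cell.

    Feature extractors are frozen after (optional) source pretraining;
    heads are trained per fold on the retained subset M1, with the dense
    head using a 70/30 train/validation split inside M1 and SVM heads
    using all of M1.  Returns a long-format results table.
    """
    rows = []
    for seed in seeds:
        record = (datasets_by_seed or {}).get(seed, dataset)
        data = binary_task_arrays(record, pos_label)
        ids, y = data["ids"], data["y"]
        pos = dict(zip(ids, y))
        idx_of = {i: j for j, i in enumerate(ids)}
        ext_cache: dict = {}
        feats_cache: dict = {}
        for name in model_names:
            info = parse_model_name(name)
            for prr in prrs:
                plan = make_partial_dropping_folds(
                    ids, k, prr, seed=seed, labels=[pos[i] for i in ids])
                for f in range(k):
                    fold = plan.fold(f)
                    tr = np.array([idx_of[i] for i in fold["M1_ids"]])
                    te = np.array([idx_of[i] for i in fold["test_ids"]])
                    y_pred = _fit_predict(info, data, tr, te, seed, ext_cache,
                                          feats_cache, head_epochs,
                                          pretrain_epochs, pretrain_n,
                                          lstm_units)
                    counts = ConfusionCounts.from_predictions(y[te], y_pred)
                    rep = compute_metrics(counts, model_name=name, prr=prr,
                                          fold=f, seed=seed)
                    rows.append({
                        "model_name": name, "prr": prr, "fold": f,
                        "seed": seed, "tp": counts.tp, "tn": counts.tn,
                        "fp": counts.fp, "fn": counts.fn,
                        "accuracy": rep.accuracy,
                        "sensitivity": rep.sensitivity,
                        "specificity": rep.specificity, "f1": rep.f1})
    return pd.DataFrame(rows)


def _fit_predict(info, data, tr, te, seed, ext_cache, feats_cache,
                 head_epochs, pretrain_epochs, pretrain_n, lstm_units):
    y = data["y"]
    if info["kind"] == "manual_svm":
        head = fit_svm_head(data["handcrafted"][tr], y[tr])
        return head.predict(data["handcrafted"][te])
    if info["kind"] == "lstm":
        net = build_recurrent_baseline(units=lstm_units, seed=seed)
        fit(net, data["sequences"][tr], y[tr], 2, _head_config(seed, head_epochs))
        return np.argmax(net.forward(data["sequences"][te]), axis=1)
    # CNN: frozen trunk features + trained head
    fkey = (info["arch"], info["pretrained"], seed)
    if fkey not in feats_cache:
        extractor = _extractor_for(info["arch"], info["pretrained"], seed,
                                   ext_cache, pretrain_epochs, pretrain_n)
        model = md.model_from_extractor(info["arch"], extractor, seed=seed)
        feats_cache[fkey] = md.extract_features(model, data["images"])
    feats = feats_cache[fkey]
    if info["head"] == "SVM":
        head = fit_svm_head(feats[tr], y[tr])
        return head.predict(feats[te])
    dense, _ = md.fit_dense_probe(feats[tr], y[tr], 2,
                                  _head_config(seed, head_epochs))
    return np.argmax(dense.forward(feats[te].astype(np.float32)), axis=1)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each metric per (model, PRR) cell."""
    metrics = ["accuracy", "sensitivity", "specificity", "f1"]
    g = results.groupby(["model_name", "prr"])[metrics]
    out = g.agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
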