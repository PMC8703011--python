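"""Bootstrap test datasets, one-vs-rest AUC and diagnostic likelihood ratios.

A test dataset is built by drawing one feature row uniformly at random from
each test drug's samples; repeating this (default 10,000 times) yields a
distribution of per-class one-vs-rest AUC values and likelihood ratios whose
medians and 2.5-97.5 percentile intervals summarize classifier performance.

Likelihood ratios use the corrected specificity s' = specificity - 1e-3 in
both formulas, LR+ = sens / (1 - s') and LR- = (1 - sens) / s', which keeps
them finite: a perfect classifier yields LR+ = 1/0.001 = 1000 and LR- = 0.
(The printed likelihood-ratio scale is therefore capped at 1000 by
construction; evaluation reports state this cap.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .risk_classifier import CLASS_ORDER

SPECIFICITY_CORRECTION = 1.0e-3


@dataclass(frozen=True)
class ConfusionStats:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def build_test_datasets(
    features: pd.DataFrame, n: int = 10000, seed: int = 0
) -> list[np.ndarray]:
    """``n`` lists of row indices into ``features``, one uniformly drawn row
    per drug; reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    groups = []
    for drug, g in features.groupby("drug", sort=False):
        if len(g) == 0:
            raise ValueError(f"drug {drug!r} has no valid sample rows")
        groups.append(g.index.to_numpy())
    datasets = []
    for _ in range(n):
        datasets.append(
            np.array([grp[rng.integers(0, len(grp))] for grp in groups])
        )
    return datasets


def roc_auc_ovr(
    labels: Sequence[str], scores: Sequence[float], target_class: str
) -> float:
    """One-vs-rest trapezoidal AUC with the target class's probability as the
    score; ties count 0.5.  NaN (undefined) if the dataset has no positive or
    no negative rows for the class."""
    y = np.array([1 if l == target_class else 0 for l in labels])
    if y.all() or not y.any():
        return math.nan
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def confusion_and_lr(
    labels: Sequence[str], predicted: Sequence[str], target_class: str
) -> tuple[ConfusionStats, float, float]:
    """One-vs-rest confusion counts and (LR+, LR-) with the 1e-3 specificity
    correction.  NaN likelihood ratios if the class has no true positives in
    the dataset."""
    y = np.array([l == target_class for l in labels])
    p = np.array([l == target_class for l in predicted])
    stats = ConfusionStats(
        tp=int((y & p).sum()), fp=int((~y & p).sum()),
        tn=int((~y & ~p).sum()), fn=int((y & ~p).sum()),
    )
    if stats.tp + stats.fn == 0:
        return stats, math.nan, math.nan
    sens = stats.sensitivity
    spec_c = stats.specificity - SPECIFICITY_CORRECTION
    lr_plus = sens / (1.0 - spec_c)
    lr_minus = (1.0 - sens) / spec_c
    return stats, lr_plus, lr_minus


def summarize(values: Sequence[float]) -> dict:
    """Median and 2.5-97.5 percentile interval, excluding undefined (NaN)
    entries (their count is reported)."""
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        raise ValueError("all values undefined")
    lo, hi = np.percentile(defined, [2.5, 97.5])
    return {
        "median": float(np.median(defined)),
        "ci95": (float(lo), float(hi)),
        "n": int(defined.size),
        "n_excluded": int(arr.size - defined.size),
    }


def evaluate_model(
    features: pd.DataFrame,
    proba: np.ndarray,
    predicted: Sequence[str],
    n_datasets: int = 10000,
    seed: int = 0,
) -> dict:
    """Full bootstrap evaluation.

    ``features`` must carry columns drug and label, with ``proba`` (n rows x 3,
    CLASS_ORDER) and ``predicted`` aligned row-wise.  Returns per-class
    summaries of AUC, LR+ and LR- over ``n_datasets`` bootstrap test datasets,
    plus per-class AUC histograms (50 bins on [0, 1]).
    """
    features = features.reset_index(drop=True)
    labels_all = features["label"].to_numpy()
    predicted = np.asarray(predicted)
    datasets = build_test_datasets(features, n=n_datasets, seed=seed)
    per_class = {c: {"auc": [], "lr_plus": [], "lr_minus": []} for c in CLASS_ORDER}
    for idx in datasets:
        labels = labels_all[idx]
        for ci, c in enumerate(CLASS_ORDER):
            per_class[c]["auc"].append(roc_auc_ovr(labels, proba[idx, ci], c))
            _, lp, lm = confusion_and_lr(labels, predicted[idx], c)
            per_class[c]["lr_plus"].append(lp)
            per_class[c]["lr_minus"].append(lm)
    report = {
        "n_datasets": n_datasets,
        "lr_plus_cap": 1.0 / SPECIFICITY_CORRECTION,
        "note": (
            "LR uses corrected specificity s' = spec - 1e-3 in both formulas; "
            "LR+ is capped at 1000 by construction."
        ),
        "classes": {},
        "histograms": {},
    }
    edges = np.linspace(0.0, 1.0, 51)
    for c in CLASS_ORDER:
        aucs = np.asarray(per_class[c]["auc"])
        report["classes"][c] = {
            "auc": summarize(aucs),
            "lr_plus": summarize(per_class[c]["lr_plus"]),
            "lr_minus": summarize(per_class[c]["lr_minus"]),
        }
        counts, _ = np.histogram(aucs[~np.isnan(aucs)], bins=edges)
        report["histograms"][c] = {
            "bin_edges": edges.tolist(),
            "counts": counts.tolist(),
        }
    return report
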