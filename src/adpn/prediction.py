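"""Discriminating the two disease groups with network expression features.

The trained case/control classifier is applied prospectively to scans of the
psychosis-free disease group (never seen in training) to obtain their
explainable maps and local expression scores.  A margin classifier on
key-region expression features, validated with subject-stratified k-fold
cross-validation, then attempts to separate psychotic from non-psychotic
disease; the conventional baseline runs the identical scheme on ROI-intensity
features of the same regions.

By default the key-region set is re-selected inside each training fold, which
is strictly leakage-free; ``fixed_key_regions`` reproduces the simpler design
where one selection made on all baseline data is reused in every fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classify import ClassifierMetrics, TrainedClassifier
from .explain import gradcam_batch, local_expression_scores, select_regions
from .volumes import Atlas, Volume

__all__ = ["CrossValReport", "prospective_expression", "predict_psychosis"]

log = logging.getLogger(__name__)


@dataclass
class CrossValReport:
    """Per-fold and pooled metrics; pooled confusion = sum of fold confusions."""

    fold_metrics: list[ClassifierMetrics]
    pooled: ClassifierMetrics
    fold_of_subject: dict = field(repr=False, default_factory=dict)
    selected_regions_per_fold: list = field(repr=False, default_factory=list)
    seed: int = 0


def prospective_expression(clf: TrainedClassifier, volumes: list[Volume],
                           atlas: Atlas, scan_ids: list[str],
                           target_class: int = 1) -> pd.DataFrame:
    """Local expression scores for scans never seen in training, computed with
    the already-trained model and a fixed target class so rows are directly
    comparable with the training-phase expression table."""
    maps = gradcam_batch(clf, list(volumes), target_class, list(scan_ids),
                         atlas.shape)
    return local_expression_scores(maps, atlas)


def _subject_folds(subjects: pd.Series, labels: np.ndarray, k: int,
                   seed: int) -> dict[str, int]:
    """Class-stratified assignment of subjects to folds; all scans of a
    subject share its fold; ties broken by subject-id order."""
    df = pd.DataFrame({"subject": subjects.to_numpy(), "label": labels})
    per_subject = df.groupby("subject")["label"].first()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    fold_of: dict[str, int] = {}
    for cls in np.unique(per_subject.to_numpy()):
        subs = sorted(per_subject.index[per_subject == cls])
        if len(subs) < k:
            raise ValueError(f"k={k} exceeds number of subjects ({len(subs)}) in class {cls}")
        subs = list(rng.permutation(subs))
        for i, s in enumerate(subs):
            fold_of[s] = i % k
    return fold_of


def predict_psychosis(expression: pd.DataFrame, groups: pd.Series,
                      subjects: pd.Series, positive_group: str, negative_group: str,
                      k_folds: int = 5, seed: int = 0,
                      feature_table: pd.DataFrame | None = None,
                      fixed_key_regions: list[int] | None = None,
                      selection_alpha: float = 0.05,
                      fallback_top_k: int = 10,
                      kernel: str = "linear") -> CrossValReport:
    """Cross-validated margin classification of the two disease groups.

    ``expression`` drives key-region selection (score of ``positive_group``
    greater, Bonferroni-corrected ``selection_alpha``); classification features
    come from ``feature_table`` restricted to those regions (defaults to the
    expression table itself; pass ROI-intensity means for the conventional
    baseline).  If a training fold yields no significant region, the
    ``fallback_top_k`` regions by |t| are used and the event is logged.
    """
    groups = pd.Series(np.asarray(groups), index=expression.index)
    subjects = pd.Series(np.asarray(subjects), index=expression.index)
    features = expression if feature_table is None else feature_table
    if not features.index.equals(expression.index):
        features = features.loc[expression.index]
    labels = (groups == positive_group).to_numpy(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both groups must be present")

    fold_of = _subject_folds(subjects, labels, k_folds, seed)
    fold_idx = subjects.map(fold_of).to_numpy()

    fold_metrics, region_sets = [], []
    pooled = ClassifierMetrics(0, 0, 0, 0)
    for fold in range(k_folds):
        te = fold_idx == fold
        tr = ~te
        if fixed_key_regions is not None:
            regions = list(fixed_key_regions)
        else:
            sel = select_regions(expression.loc[tr], groups.loc[tr],
                                 (positive_group, negative_group),
                                 direction=positive_group, alpha=selection_alpha)
            regions = sel.selected_region_ids
            if not regions:
                ranked = sel.table.reindex(sel.table["t"].abs().sort_values(ascending=False).index)
                regions = [int(r) for r in ranked["region_id"].head(fallback_top_k)]
                log.info("fold %d: no Bonferroni-significant region; using top-%d by |t|",
                         fold, fallback_top_k)
        region_sets.append(regions)

        X = features[regions].to_numpy(float)
        clf = make_pipeline(StandardScaler(), SVC(kernel=kernel, C=1.0))
        clf.fit(X[tr], labels[tr])
        m = ClassifierMetrics.from_predictions(labels[te], clf.predict(X[te]))
        fold_metrics.append(m)
        pooled = pooled + m

    return CrossValReport(fold_metrics=fold_metrics, pooled=pooled,
                          fold_of_subject=fold_of,
                          selected_regions_per_fold=region_sets, seed=seed)
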